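"""Screening for metabolites and genes of interest.

Molecules of interest are the union of (i) differentially expressed (DE)
molecules between two sample classes — metabolites by Wilcoxon rank-sum test,
genes by the SAM (significance analysis of microarrays) permutation procedure
— and (ii) molecules participating in at least one high Pearson-correlation
pair (metabolite–metabolite, metabolite–gene or gene–gene).

Expression/abundance data are pandas DataFrames with molecule ids as the row
index, sample ids as columns, and NaN marking missing abundances; group
labels are a pandas Series mapping sample id to one of exactly two class
labels.  All correlations are computed on pairwise-complete observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: provenance flags
DE = "DE"
HIGH_CORR = "HIGH_CORR"


class AlignmentError(ValueError):
    """Sample sets of the two matrices do not match."""


def validate_matrix(matrix: pd.DataFrame, name: str = "matrix") -> None:
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate molecule ids {dups}")
    if matrix.columns.has_duplicates:
        raise ValueError(f"{name}: duplicate sample ids")


def validate_labels(labels: pd.Series, *matrices: pd.DataFrame) -> tuple[str, str]:
    """Check the two-class contract; returns the class labels sorted."""
    classes = sorted(pd.unique(labels.dropna()))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 samples")
    for m in matrices:
        missing = [s for s in labels.index if s not in m.columns]
        if missing:
            raise ValueError(f"labelled samples absent from matrix: {missing}")
    return classes[0], classes[1]


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    The exact null distribution is enumerated for small untied samples
    (n_a + n_b <= 12, no ties); otherwise the normal approximation with tie
    and continuity corrections is used.  Rank-based, hence invariant under
    strictly monotone transforms of the pooled data.  Completely tied data
    yield p = 1 with a degeneracy warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 finite values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p set to 1")
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def de_screen_wilcoxon(matrix: pd.DataFrame, labels: pd.Series,
                       p_cutoff: float = 0.05) -> tuple[set[str], pd.Series]:
    """Per-molecule Wilcoxon screen; returns (selected ids, p-value Series)."""
    cls_a, cls_b = validate_labels(labels, matrix)
    a_cols = labels.index[labels == cls_a]
    b_cols = labels.index[labels == cls_b]
    pvals = {}
    for mol, row in matrix.iterrows():
        va = row[a_cols].to_numpy(dtype=float)
        vb = row[b_cols].to_numpy(dtype=float)
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if len(va) < 2 or len(vb) < 2:
            pvals[mol] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals[mol] = wilcoxon_rank_sum(va, vb)
    p = pd.Series(pvals, name="p_wilcoxon")
    selected = set(p.index[p < p_cutoff])
    return selected, p


@dataclass
class SamResult:
    """Outcome of one SAM screen."""

    d: pd.Series                    # moderated d-statistic per molecule
    s0: float                       # fudge factor (Tusher percentile rule)
    delta: float | None             # selected |d| threshold (None: nothing passes)
    fdr_at_delta: float | None
    selected: set[str] = field(default_factory=set)
    zero_variance: set[str] = field(default_factory=set)


def _sam_d(values: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray,
           s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Moderated difference statistic d_i = (mean_b - mean_a)/(s_i + s0)."""
    xa, xb = values[:, a_idx], values[:, b_idx]
    na, nb = xa.shape[1], xb.shape[1]
    r = np.nanmean(xb, axis=1) - np.nanmean(xa, axis=1)
    ssa = np.nansum((xa - np.nanmean(xa, axis=1, keepdims=True)) ** 2, axis=1)
    ssb = np.nansum((xb - np.nanmean(xb, axis=1, keepdims=True)) ** 2, axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, r / denom, 0.0)
    return d, s


def _tusher_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor minimising the coefficient of variation of d across the
    spread of per-molecule standard errors (percentile-minimisation rule)."""
    alphas = np.arange(0.0, 1.01, 0.05)
    candidates = np.quantile(s, alphas)
    # bin molecules by s into up to 20 quantile windows
    n_bins = min(20, max(2, len(s) // 10))
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for s0 in candidates:
        denom = s + s0
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(denom > 0, r / denom, 0.0)
        mads = []
        for k in range(n_bins):
            dk = d[bins == k]
            if len(dk) >= 2:
                mads.append(stats.median_abs_deviation(dk, scale="normal"))
        mads = np.asarray(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads, ddof=0) / np.mean(mads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_screen(matrix: pd.DataFrame, labels: pd.Series,
               fdr_cutoff: float = 0.001, n_perm: int = 100,
               seed: int = 0, s0: float | None = None) -> SamResult:
    """SAM permutation screen for differential expression.

    Computes the moderated d-statistic per molecule (mean difference over
    pooled standard error plus fudge factor ``s0``, the latter chosen by the
    percentile-minimisation rule unless given), estimates the FDR at each
    candidate |d| threshold as the median permutation exceedance count over
    the observed exceedance count, and selects the smallest threshold whose
    estimated FDR is <= ``fdr_cutoff``.  Fully reproducible under ``seed``.
    """
    if n_perm < 25:
        raise ValueError("n_perm must be >= 25")
    cls_a, cls_b = validate_labels(labels, matrix)
    cols = list(labels.index)
    values = matrix[cols].to_numpy(dtype=float)
    lab = labels[cols].to_numpy()
    a_idx = np.flatnonzero(lab == cls_a)
    b_idx = np.flatnonzero(lab == cls_b)

    r = (np.nanmean(values[:, b_idx], axis=1)
         - np.nanmean(values[:, a_idx], axis=1))
    _, s = _sam_d(values, a_idx, b_idx, 0.0)
    if s0 is None:
        s0 = _tusher_s0(r, s)
    d_obs, s = _sam_d(values, a_idx, b_idx, s0)
    zero_var = set(matrix.index[(s + s0) == 0])
    if zero_var:
        logger.warning("%d zero-variance molecules assigned d=0", len(zero_var))

    rng = np.random.default_rng(seed)
    n = len(cols)
    abs_obs = np.sort(np.abs(d_obs))[::-1]
    perm_abs = np.empty((n_perm, len(d_obs)))
    for p in range(n_perm):
        perm = rng.permutation(n)
        d_p, _ = _sam_d(values, perm[: len(a_idx)], perm[len(a_idx):], s0)
        perm_abs[p] = np.abs(d_p)
    perm_sorted = np.sort(perm_abs, axis=1)

    # candidate thresholds: observed |d| values, descending
    delta, fdr_at = None, None
    n_mol = perm_sorted.shape[1]
    for t in np.unique(abs_obs)[::-1]:
        n_obs = int(np.sum(np.abs(d_obs) >= t))
        if n_obs == 0:
            continue
        exceed = np.array([n_mol - np.searchsorted(perm_sorted[p], t, side="left")
                           for p in range(n_perm)])
        fdr = float(np.median(exceed)) / n_obs
        if fdr <= fdr_cutoff:
            delta, fdr_at = float(t), fdr
        else:
            break
    d_series = pd.Series(d_obs, index=matrix.index, name="d_sam")
    selected = set() if delta is None else set(
        matrix.index[np.abs(d_obs) >= delta]
    )
    return SamResult(d=d_series, s0=float(s0), delta=delta,
                     fdr_at_delta=fdr_at, selected=selected,
                     zero_variance=zero_var)


# ---------------------------------------------------------------------------
# Correlation screen
# ---------------------------------------------------------------------------

def pearson_corr(x, y, min_periods: int = 3) -> float:
    """Pearson product-moment correlation on pairwise-complete observations.

    Returns NaN (an "undefined" sentinel, never 0) when either profile has
    zero variance over the complete pairs or fewer than ``min_periods``
    complete pairs exist.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_periods:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    return float(stats.pearsonr(xs, ys).statistic)


def pairwise_pcc(block: np.ndarray, other: np.ndarray,
                 min_periods: int = 5) -> np.ndarray:
    """Pairwise-complete Pearson correlations between every row of ``block``
    and every row of ``other`` (NaN-aware, vectorised).

    Entries with fewer than ``min_periods`` shared finite samples or zero
    variance on the complete pairs are NaN.
    """
    ma = np.isfinite(block)
    mb = np.isfinite(other)
    a0 = np.where(ma, block, 0.0)
    b0 = np.where(mb, other, 0.0)
    n = ma.astype(float) @ mb.T.astype(float)
    sx = a0 @ mb.T.astype(float)
    sy = ma.astype(float) @ b0.T
    sxy = a0 @ b0.T
    sxx = (a0 ** 2) @ mb.T.astype(float)
    syy = ma.astype(float) @ (b0 ** 2).T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx ** 2 / n
        vy = syy - sy ** 2 / n
        r = cov / np.sqrt(vx * vy)
    bad = (n < min_periods) | (vx <= 0) | (vy <= 0)
    r = np.where(bad, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def correlation_screen(metab: pd.DataFrame, gene: pd.DataFrame,
                       cutoff: float = 0.8, use_abs: bool = False,
                       min_periods: int = 5,
                       block_size: int | None = None
                       ) -> tuple[set[str], set[str]]:
    """Molecules participating in >= 1 high-correlation pair.

    All metabolite–metabolite, metabolite–gene and gene–gene pairs are
    scanned; a molecule qualifies when any pair (excluding self-pairs and
    pairs with < ``min_periods`` shared samples) has signed Pcc > ``cutoff``
    (or |Pcc| > cutoff with ``use_abs``).  ``block_size`` switches to a
    row-blocked scan with identical results and bounded memory.
    """
    validate_matrix(metab, "metabolite matrix")
    validate_matrix(gene, "gene matrix")
    if set(metab.columns) != set(gene.columns):
        only_m = sorted(set(metab.columns) - set(gene.columns))
        only_g = sorted(set(gene.columns) - set(metab.columns))
        raise AlignmentError(
            f"sample sets differ: only in metabolite matrix {only_m}, "
            f"only in gene matrix {only_g}")
    gene = gene[metab.columns]
    combined = pd.concat([metab, gene])
    if combined.index.has_duplicates:
        raise ValueError("metabolite and gene ids must not collide")
    x = combined.to_numpy(dtype=float)
    n_mol = x.shape[0]
    hits = np.zeros(n_mol, dtype=bool)
    step = block_size or n_mol
    for start in range(0, n_mol, step):
        blk = slice(start, min(start + step, n_mol))
        r = pairwise_pcc(x[blk], x, min_periods=min_periods)
        rows = np.arange(blk.start, blk.stop)
        r[rows - blk.start, rows] = np.nan  # exclude self-pairs
        passing = (np.abs(r) > cutoff) if use_abs else (r > cutoff)
        passing &= np.isfinite(r)
        hits[blk] |= passing.any(axis=1)
        hits |= passing.any(axis=0)
    ids = combined.index.to_numpy()
    hit_ids = set(ids[hits])
    return hit_ids & set(metab.index), hit_ids & set(gene.index)


# ---------------------------------------------------------------------------
# Interest set
# ---------------------------------------------------------------------------

@dataclass
class InterestSet:
    """Union of DE and high-correlation molecules with provenance flags."""

    metabolites: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def flags(self, molecule_id: str) -> set[str]:
        return self.provenance.get(molecule_id, set())


def build_interest_set(de_metab: set[str], de_gene: set[str],
                       corr_metab: set[str], corr_gene: set[str]) -> InterestSet:
    """Union DE and high-correlation molecules, tracking provenance.

    Idempotent and commutative in its inputs; |union| lies between
    max(|A|,|B|) and |A|+|B| for each kind.
    """
    prov: dict[str, set[str]] = {}
    for mol in set(de_metab) | set(de_gene):
        prov.setdefault(mol, set()).add(DE)
    for mol in set(corr_metab) | set(corr_gene):
        prov.setdefault(mol, set()).add(HIGH_CORR)
    return InterestSet(metabolites=set(de_metab) | set(corr_metab),
                       genes=set(de_gene) | set(corr_gene),
                       provenance=prov)


def interest_table(interest: InterestSet,
                   stats_by_molecule: dict[str, tuple[float, float]] | None = None
                   ) -> pd.DataFrame:
    """Tabular view (id, kind, flags, statistic, p_or_fdr) for TSV export."""
    rows = []
    for mol in sorted(interest.metabolites):
        stat, p = (stats_by_molecule or {}).get(mol, (np.nan, np.nan))
        rows.append((mol, "metabolite", ";".join(sorted(interest.flags(mol))),
                     stat, p))
    for mol in sorted(interest.genes):
        stat, p = (stats_by_molecule or {}).get(mol, (np.nan, np.nan))
        rows.append((mol, "gene", ";".join(sorted(interest.flags(mol))), stat, p))
    return pd.DataFrame(rows, columns=["id", "kind", "flags", "statistic",
                                       "p_or_fdr"])
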