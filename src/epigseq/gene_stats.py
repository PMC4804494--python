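"""Per-gene magnitude-of-change, dispersion and model-based significance.

Magnitude of change of a gene in a treated group versus control is measured by
the Z statistic of a Wilcoxon rank-sum test (normal approximation with tie and
continuity corrections) on the reads-per-million scale.  With fewer than
``small_n_cutoff`` replicates per group the normal approximation is unreliable
and the Hodges-Lehmann location-shift estimator (median of all pairwise
differences) on the log2(RPM + 1) scale is used instead, so the magnitude
reads as an approximate log2 fold change.

Dispersion is the quasi-Poisson scale factor theta of the variance function
V(Y) = mu * theta, estimated from a Poisson generalized linear model of the
counts on the group factor with a log library-size offset.  Because the model
is a single saturated factor, the IRLS fit has a closed form: the fitted rate
of a group is its total count over its total library size.  theta is the
Pearson chi-square divided by the residual degrees of freedom, and the
per-gene p-value is the dispersion-adjusted F test of the group factor against
the intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .io_counts import CountMatrix

__all__ = [
    "GeneStatsTable",
    "wilcoxon_z",
    "hodges_lehmann",
    "magnitude_vector",
    "quasipoisson_dispersion",
    "glm_gene_pvalue",
    "compute_gene_stats",
]

#: Below this many replicates per group the rank-sum normal approximation is
#: considered unreliable and the Hodges-Lehmann estimator is used.
DEFAULT_SMALL_N_CUTOFF = 4

METHOD_WILCOXON = "wilcoxon_z"
METHOD_HL = "hodges_lehmann"


@dataclass
class GeneStatsTable:
    """Per-gene statistics for every gene of a count matrix.

    ``magnitudes`` has one column per treated group (NaN for all-zero genes),
    ``signs`` holds the thresholded directions in {-1, 0, +1}, ``dispersion``
    the quasi-Poisson theta, ``p_value`` the GLM group-effect p-value.
    """

    magnitudes: np.ndarray
    signs: np.ndarray
    method: str
    dispersion: np.ndarray
    p_value: np.ndarray
    treated_groups: list
    st: float


def wilcoxon_z(treated, control) -> float:
    """Normal-approximation Z of the Wilcoxon rank-sum test.

    Positive when the treated values rank above the control values.  Ties are
    handled by midranks with the tie-corrected variance; a 0.5 continuity
    correction shrinks the statistic toward zero.  Returns 0 when every value
    is tied across both sides.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ValueError("need at least 2 values per side")
    n1, n2 = treated.size, control.size
    pooled = np.concatenate([treated, control])
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    d = w - mu
    if d == 0:
        return 0.0
    return float((d - 0.5 * np.sign(d)) / np.sqrt(var))


def hodges_lehmann(treated, control) -> float:
    """Hodges-Lehmann location shift: median of all pairwise differences
    ``treated_i - control_j``."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 1 or control.size < 1:
        raise ValueError("need at least 1 value per side")
    return float(np.median(np.subtract.outer(treated, control)))


def _hl_scale(cm: CountMatrix) -> np.ndarray:
    """log2(RPM + 1) matrix on which Hodges-Lehmann shifts are computed."""
    return np.log2(cm.rpm() + 1.0)


def magnitude_vector(gene_index: int, cm: CountMatrix,
                     small_n_cutoff: int = DEFAULT_SMALL_N_CUTOFF,
                     st: float = 2.0):
    """Magnitude statistic of one gene in each treated group versus control.

    Returns ``(magnitudes, method, signs)``.  The method is Hodges-Lehmann on
    the log2(RPM + 1) scale iff the smallest per-group replicate count is
    below ``small_n_cutoff``, otherwise the Wilcoxon Z on the RPM scale.
    Signs are ``sign(magnitude)`` where ``|magnitude| >= st``, else 0.
    """
    stats = compute_gene_stats(
        cm, small_n_cutoff=small_n_cutoff, st=st,
        gene_subset=np.array([gene_index]), skip_model=True,
    )
    return stats.magnitudes[gene_index], stats.method, stats.signs[gene_index]


# ---------------------------------------------------------------------------
# quasi-Poisson one-factor GLM (closed form)
# ---------------------------------------------------------------------------

def _group_onehot(cm: CountMatrix) -> np.ndarray:
    groups = cm.group_names()
    member = np.zeros((len(groups), cm.n_samples))
    for k, g in enumerate(groups):
        member[k, cm.group_columns(g)] = 1.0
    return member


def _qp_fit(counts: np.ndarray, cm: CountMatrix):
    """Fitted means, Pearson theta, deviances of the one-factor quasi-Poisson
    model for many genes at once.

    Returns ``(theta, dev_full, dev_null, df_resid, n_groups)``.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    L = cm.library_sizes.astype(float)
    member = _group_onehot(cm)            # (G, S)
    n_groups, n_samples = member.shape
    group_tot = counts @ member.T         # (genes, G)
    group_lib = member @ L                # (G,)
    rates = group_tot / group_lib         # fitted rate per group
    mu = (rates @ member) * L             # (genes, S) fitted means
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.where(mu > 0, (counts - mu) ** 2 / mu, 0.0).sum(axis=1)
        xlogx = np.where(counts > 0, counts * np.log(np.where(counts > 0, counts / np.where(mu > 0, mu, 1.0), 1.0)), 0.0)
    dev_full = 2.0 * (xlogx - (counts - mu)).sum(axis=1)
    null_rate = counts.sum(axis=1, keepdims=True) / L.sum()
    mu0 = null_rate * L
    with np.errstate(divide="ignore", invalid="ignore"):
        xlogx0 = np.where(counts > 0, counts * np.log(np.where(counts > 0, counts / np.where(mu0 > 0, mu0, 1.0), 1.0)), 0.0)
    dev_null = 2.0 * (xlogx0 - (counts - mu0)).sum(axis=1)
    df_resid = n_samples - n_groups
    theta = pearson / df_resid if df_resid > 0 else np.full(counts.shape[0], np.nan)
    return theta, dev_full, dev_null, df_resid, n_groups


def quasipoisson_dispersion(gene, cm: CountMatrix) -> float:
    """Quasi-Poisson dispersion theta of one gene profile.

    ``theta = Pearson chi-square / residual df`` from the group-factor model
    with a log library-size offset; 0 when the counts match the fitted group
    means exactly.  Raises on an all-zero profile.
    """
    gene = np.asarray(gene, dtype=float)
    if (gene == 0).all():
        raise ValueError("dispersion undefined for an all-zero gene profile")
    theta, *_ = _qp_fit(gene[None, :], cm)
    return float(theta[0])


def glm_gene_pvalue(gene, cm: CountMatrix) -> float:
    """Dispersion-adjusted F-test p-value of the group factor for one gene.

    ``F = ((D_null - D_full) / (G - 1)) / theta`` referred to an
    F(G-1, n-G) distribution, where D are Poisson deviances.  Returns 1 for a
    gene with no between-group deviance (e.g. identical counts everywhere).
    """
    gene = np.asarray(gene, dtype=float)
    if (gene == 0).all():
        raise ValueError("p-value undefined for an all-zero gene profile")
    theta, dev_full, dev_null, df_resid, n_groups = _qp_fit(gene[None, :], cm)
    return float(_f_pvalues(theta, dev_full, dev_null, df_resid, n_groups)[0])


def _f_pvalues(theta, dev_full, dev_null, df_resid, n_groups):
    diff = np.maximum(dev_null - dev_full, 0.0)
    df1 = n_groups - 1
    p = np.full(theta.shape, np.nan)
    if df_resid <= 0 or df1 <= 0:
        return p
    zero_theta = theta <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (diff / df1) / np.where(zero_theta, np.nan, theta)
    p = sps.f.sf(F, df1, df_resid)
    # an exact fit with no group effect is a p of 1; an exact fit with a
    # group effect is overwhelming evidence
    p = np.where(zero_theta & (diff <= 1e-12), 1.0, p)
    p = np.where(zero_theta & (diff > 1e-12), 0.0, p)
    return p


# ---------------------------------------------------------------------------
# whole-matrix driver
# ---------------------------------------------------------------------------

def compute_gene_stats(cm: CountMatrix,
                       small_n_cutoff: int = DEFAULT_SMALL_N_CUTOFF,
                       st: float = 2.0,
                       gene_subset=None,
                       skip_model: bool = False) -> GeneStatsTable:
    """Compute magnitudes, signs, dispersion and GLM p-values for all genes.

    All-zero genes receive NaN statistics and zero signs.  ``gene_subset``
    restricts the computation (other rows stay NaN); ``skip_model`` omits the
    GLM quantities.
    """
    groups = cm.treated_groups()
    n_genes = cm.n_genes
    magnitudes = np.full((n_genes, len(groups)), np.nan)
    signs = np.zeros((n_genes, len(groups)), dtype=int)
    dispersion = np.full(n_genes, np.nan)
    p_value = np.full(n_genes, np.nan)

    if gene_subset is None:
        gene_subset = np.arange(n_genes)
    gene_subset = np.asarray(gene_subset, dtype=int)
    active = gene_subset[~cm.all_zero[gene_subset]]

    min_reps = min(len(cm.group_columns(g)) for g in cm.group_names())
    method = METHOD_HL if min_reps < small_n_cutoff else METHOD_WILCOXON

    ctrl_cols = cm.group_columns(cm.control_label)
    if method == METHOD_HL:
        scale = _hl_scale(cm)
        for k, g in enumerate(groups):
            cols = cm.group_columns(g)
            # median over all pairwise treated-control differences, vectorised
            diffs = scale[np.ix_(active, cols)][:, :, None] - scale[np.ix_(active, ctrl_cols)][:, None, :]
            magnitudes[active, k] = np.median(diffs.reshape(len(active), -1), axis=1)
    else:
        rpm = cm.rpm()
        for k, g in enumerate(groups):
            cols = cm.group_columns(g)
            for i in active:
                magnitudes[i, k] = wilcoxon_z(rpm[i, cols], rpm[i, ctrl_cols])

    with np.errstate(invalid="ignore"):
        thresholded = np.abs(magnitudes) >= st
    signs = np.where(thresholded, np.sign(magnitudes), 0).astype(int)

    if not skip_model and len(active):
        theta, dev_full, dev_null, df_resid, n_groups_all = _qp_fit(
            cm.counts[active].astype(float), cm
        )
        dispersion[active] = theta
        p_value[active] = _f_pvalues(theta, dev_full, dev_null, df_resid, n_groups_all)

    return GeneStatsTable(
        magnitudes=magnitudes, signs=signs, method=method,
        dispersion=dispersion, p_value=p_value,
        treated_groups=groups, st=st,
    )
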