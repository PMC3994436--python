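"""Joint inference of absolute copy number, mutant multiplicity and
sample-wide purity/ploidy scaling from DNA allele fractions and
tumor:germline coverage ratios.

Two observations constrain each SNV. First, its allele fraction can only
take the discrete lattice values

    f(cn, m) = m * rho / (cn * rho + 2 * (1 - rho)),   1 <= m <= cn,

because m of the cn tumor copies carry the mutant base and contaminating
normal cells (fraction 1 - rho of the sample) contribute two wild-type
copies. Second, the tumor:germline exome coverage ratio at the locus is
proportional to the locus copy content, E[r] = (rho*cn + 2*(1-rho)) / c,
where c is a free per-sample scale (absorbing mean ploidy and library
sizes) shared by all loci.

The fit is a grid search over purity rho and scale c; at each candidate,
every SNV is assigned its maximum-likelihood lattice point, combining the
binomial log-likelihood of the mutant read count at the lattice fraction
with a Gaussian log-likelihood of the log coverage ratio (delta-method
variance 1/n_tumor + 1/n_germline). The sample mean ploidy psi is reported
as the SNV-weighted mean of the fitted copy numbers.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.special import xlogy

from .core import AlleleCounts, AlleleFractionEstimate, LatticeFit, SampleModel

DEFAULT_CN_MAX = 5
DEFAULT_RHO_GRID = np.round(np.arange(0.10, 1.0001, 0.05), 2)


def lattice(cn_max: int = DEFAULT_CN_MAX, purity: float = 1.0) -> list[tuple[int, int, float]]:
    """All (cn, m, expected allele fraction) lattice points up to cn_max.

    Duplicate fractions (e.g. 1/2 and 2/4 in a pure sample) are retained
    with their distinct (cn, m) identities; points are ordered by (cn, m),
    which downstream argmax tie-breaking relies on (parsimony: smaller cn,
    then smaller m, wins exact ties).
    """
    if cn_max < 1:
        raise ValueError(f"cn_max must be >= 1, got {cn_max}")
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    pts = []
    for cn in range(1, cn_max + 1):
        denom = cn * purity + 2.0 * (1.0 - purity)
        for m in range(1, cn + 1):
            pts.append((cn, m, m * purity / denom))
    return pts


def coverage_ratio(
    tumor_dna: Iterable[AlleleCounts], germline_dna: Iterable[AlleleCounts]
) -> float:
    """Replicate-summed tumor over germline total read counts at a locus."""
    n_t = sum(c.total_reads for c in tumor_dna)
    n_g = sum(c.total_reads for c in germline_dna)
    if n_g == 0:
        raise ValueError("zero germline coverage; locus belongs in the germline filter")
    return n_t / n_g


def _lattice_arrays(cn_max: int, purity: float):
    pts = lattice(cn_max, purity)
    cn = np.array([p[0] for p in pts])
    m = np.array([p[1] for p in pts])
    f = np.array([p[2] for p in pts])
    return cn, m, f


def _loglik_matrix(
    k: np.ndarray,
    n: np.ndarray,
    log_ratio: np.ndarray,
    var_log_ratio: np.ndarray,
    purity: float,
    scale: float,
    cn_max: int,
    coverage_weight: float,
) -> np.ndarray:
    """(n_snv, n_lattice) log-likelihood of each lattice point per SNV."""
    cn, _, f = _lattice_arrays(cn_max, purity)
    bin_ll = xlogy(k[:, None], f[None, :]) + xlogy(
        (n - k)[:, None], 1.0 - f[None, :]
    )
    mu = np.log(purity * cn + 2.0 * (1.0 - purity)) - np.log(scale)
    resid = log_ratio[:, None] - mu[None, :]
    cov_ll = -0.5 * resid**2 / var_log_ratio[:, None] - 0.5 * np.log(
        2.0 * np.pi * var_log_ratio[:, None]
    )
    return bin_ll + coverage_weight * cov_ll


def _unpack_afs(afs: Sequence[AlleleFractionEstimate]):
    n = np.array([a.n_effective for a in afs], dtype=float)
    k = np.rint(np.array([a.p for a in afs]) * n)
    return k, n


def fit_sample_model(
    ratios: Sequence[float],
    afs: Sequence[AlleleFractionEstimate],
    *,
    germline_totals: Sequence[float] | None = None,
    cn_max: int = DEFAULT_CN_MAX,
    rho_grid: Sequence[float] | None = None,
    n_scale_grid: int = 41,
    coverage_weight: float = 1.0,
) -> SampleModel:
    """Grid-search purity rho and coverage scale c maximizing the total
    log-likelihood of all SNVs at their best lattice points.

    ``afs`` are pooled (replicate-combined) tumor DNA allele fractions;
    ``ratios`` the matched tumor:germline coverage ratios. Germline totals
    default to tumor_total/ratio when not given. With fewer than ~20 SNVs
    or a degenerate input set the purity may not be identifiable; flags on
    the returned model record this.
    """
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) != len(afs):
        raise ValueError("ratios and allele fractions must align")
    if len(afs) == 0:
        raise ValueError("no SNVs to fit")
    k, n = _unpack_afs(afs)
    n_g = (
        np.asarray(germline_totals, dtype=float)
        if germline_totals is not None
        else n / ratios
    )
    log_ratio = np.log(ratios)
    var_lr = 1.0 / np.maximum(n, 1.0) + 1.0 / np.maximum(n_g, 1.0)

    rho_grid = DEFAULT_RHO_GRID if rho_grid is None else np.asarray(rho_grid, dtype=float)
    r_med = float(np.median(ratios))
    content_grid = np.linspace(1.0, float(cn_max), n_scale_grid)

    # iterate purity high-to-low so exact likelihood ties resolve toward the
    # purest (least contaminated) explanation, which also makes the diploid
    # degenerate case land on cn=2 rather than an equivalent impure solution
    best = None  # (total_ll, rho, c)
    per_rho_best: dict[float, float] = {}
    for rho in sorted(np.asarray(rho_grid, dtype=float), reverse=True):
        cn_arr, _, f = _lattice_arrays(cn_max, rho)
        bin_ll = xlogy(k[:, None], f[None, :]) + xlogy((n - k)[:, None], 1.0 - f[None, :])
        mu_base = np.log(rho * cn_arr + 2.0 * (1.0 - rho))
        for content in content_grid:
            c = (rho * content + 2.0 * (1.0 - rho)) / r_med
            mu = mu_base - np.log(c)
            resid = log_ratio[:, None] - mu[None, :]
            cov_ll = -0.5 * resid**2 / var_lr[:, None] - 0.5 * np.log(
                2.0 * np.pi * var_lr[:, None]
            )
            total = float((bin_ll + coverage_weight * cov_ll).max(axis=1).sum())
            per_rho_best[rho] = max(per_rho_best.get(rho, -np.inf), total)
            if best is None or total > best[0]:
                best = (total, float(rho), float(c))

    total_ll, rho_hat, c_hat = best
    ll_mat = _loglik_matrix(
        k, n, log_ratio, var_lr, rho_hat, c_hat, cn_max, coverage_weight
    )
    cn_arr, _, _ = _lattice_arrays(cn_max, rho_hat)
    psi = float(np.mean(cn_arr[np.argmax(ll_mat, axis=1)]))

    flags: list[str] = []
    near = [r for r, ll in per_rho_best.items() if ll >= total_ll - 1e-6]
    if len(near) > 1:
        flags.append("rho_unidentifiable")
    if len(np.unique(np.column_stack([k, n, ratios]), axis=0)) == 1:
        flags.append("degenerate_input")
        warnings.warn("all SNVs identical; sample model poorly constrained")
    if len(afs) < 20:
        flags.append("few_snvs")

    return SampleModel(
        purity=rho_hat, psi=psi, coverage_scale=c_hat, loglik=total_ll, flags=flags
    )


def assign_cn(
    af: AlleleFractionEstimate,
    ratio: float,
    model: SampleModel,
    cn_max: int = DEFAULT_CN_MAX,
    coverage_weight: float = 1.0,
    germline_total: float | None = None,
) -> LatticeFit:
    """Maximum-likelihood (copy number, multiplicity) for one SNV.

    Combines the binomial likelihood of the pooled mutant read count at
    each lattice fraction with the Gaussian likelihood of the log coverage
    ratio; exact ties break toward smaller cn, then smaller m.
    """
    k, n = _unpack_afs([af])
    n_g = np.array([germline_total if germline_total is not None else n[0] / ratio])
    log_ratio = np.array([np.log(ratio)])
    var_lr = 1.0 / np.maximum(n, 1.0) + 1.0 / np.maximum(n_g, 1.0)
    ll = _loglik_matrix(
        k, n, log_ratio, var_lr, model.purity, model.coverage_scale, cn_max, coverage_weight
    )[0]
    cn_arr, m_arr, _ = _lattice_arrays(cn_max, model.purity)
    i_best = int(np.argmax(ll))  # first max = smallest (cn, m): parsimony tie-break
    others = np.delete(ll, i_best)
    margin = float(ll[i_best] - others.max()) if others.size else float("inf")
    return LatticeFit(
        cn=int(cn_arr[i_best]), m=int(m_arr[i_best]), loglik=float(ll[i_best]),
        runner_up_margin=margin,
    )


def assign_all(
    afs: Sequence[AlleleFractionEstimate],
    ratios: Sequence[float],
    model: SampleModel,
    cn_max: int = DEFAULT_CN_MAX,
    coverage_weight: float = 1.0,
    germline_totals: Sequence[float] | None = None,
) -> list[LatticeFit]:
    """Vectorized :func:`assign_cn` over many SNVs."""
    ratios = np.asarray(ratios, dtype=float)
    k, n = _unpack_afs(afs)
    n_g = (
        np.asarray(germline_totals, dtype=float)
        if germline_totals is not None
        else n / ratios
    )
    var_lr = 1.0 / np.maximum(n, 1.0) + 1.0 / np.maximum(n_g, 1.0)
    ll = _loglik_matrix(
        k, n, np.log(ratios), var_lr, model.purity, model.coverage_scale,
        cn_max, coverage_weight,
    )
    cn_arr, m_arr, _ = _lattice_arrays(cn_max, model.purity)
    out = []
    for row in ll:
        i = int(np.argmax(row))
        others = np.delete(row, i)
        margin = float(row[i] - others.max()) if others.size else float("inf")
        out.append(
            LatticeFit(cn=int(cn_arr[i]), m=int(m_arr[i]), loglik=float(row[i]),
                       runner_up_margin=margin)
        )
    return out
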