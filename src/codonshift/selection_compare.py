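"""Comparing fitted selection coefficients between two region fits.

Workflow: pick each family's most selectively-favored codon from the null
(merged-region) fit, rescale every region fit's draws relative to that codon,
then summarize the difference between two regions by Deming (errors-in-both-
variables) regression, Spearman rank correlation, per-codon posterior-interval
shift calls, and a one-tailed exact binomial false-positive audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from codonshift.codon_core import CodonFamilyTable
from codonshift.fit_mcmc import McmcSettings, PosteriorSamples, posterior_interval

__all__ = [
    "DemingFit",
    "ShiftCall",
    "ComparisonReport",
    "select_favored_codons",
    "rescale_to_reference",
    "deming_fit",
    "detect_shifts",
    "spearman_corr",
    "binomial_fp_test",
    "compare_regions",
]

logger = logging.getLogger(__name__)


@dataclass
class DemingFit:
    slope: float
    intercept: float
    ci: tuple[float, float]  # 95% CI for the slope
    lam: float               # error-variance ratio var(y-errors)/var(x-errors)
    n: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if not self.ci[0] <= self.slope <= self.ci[1]:
            raise ValueError("CI must contain the slope estimate")


@dataclass(frozen=True)
class ShiftCall:
    codon: str
    family_id: str
    direction: int  # sign(mean_B - mean_A)


def select_favored_codons(
    null_samples: PosteriorSamples, table: CodonFamilyTable
) -> dict[str, str]:
    """Most selectively-favored codon per family from the null fit.

    Smaller delta_eta means more favored (the model uses exp(-deta*phi));
    the fitting reference codon contributes an implicit 0.  Exact ties break
    alphabetically and are logged.
    """
    means = null_samples.posterior_mean()
    favored: dict[str, str] = {}
    for fam in table.families:
        vals = [(means.get(c, 0.0), c) for c in sorted(fam.codons)]
        best = min(vals)
        ties = [c for v, c in vals if v == best[0]]
        if len(ties) > 1:
            logger.info(
                "family %s: favored-codon tie between %s; using %s",
                fam.family_id, ties, best[1],
            )
        favored[fam.family_id] = best[1]
    return favored


def _family_draw_matrix(
    samples: PosteriorSamples, codons: Sequence[str]
) -> np.ndarray:
    """Draws for every codon of a family; absent (reference) codons are 0."""
    cols = []
    for c in codons:
        if c in samples.param_names:
            cols.append(samples.column(c))
        else:
            cols.append(np.zeros(samples.n_draws))
    return np.column_stack(cols)


def rescale_to_reference(
    samples: PosteriorSamples,
    favored: Mapping[str, str],
    table: CodonFamilyTable,
) -> PosteriorSamples:
    """Re-express draws relative to the null-fit favored codon of each family.

    The favored codon's rescaled delta_eta is identically 0; negative values
    in a region fit indicate a region-specific change in the favored codon.
    Rescaling is draw-wise and idempotent.
    """
    names: list[str] = []
    blocks: list[np.ndarray] = []
    for fam in table.families:
        if fam.family_id not in favored:
            raise ValueError(f"no favored codon supplied for family {fam.family_id}")
        ref = favored[fam.family_id]
        if ref not in fam.codons:
            raise ValueError(
                f"favored codon {ref} not in family {fam.family_id}"
            )
        mat = _family_draw_matrix(samples, fam.codons)
        mat = mat - mat[:, fam.codons.index(ref)][:, None]
        names.extend(fam.codons)
        blocks.append(mat)
    return PosteriorSamples(
        param_names=names,
        draws=np.hstack(blocks),
        deviance=samples.deviance.copy(),
        seed=samples.seed,
        settings=samples.settings,
        acceptance_rates=dict(samples.acceptance_rates),
        warnings=list(samples.warnings),
    )


def deming_fit(
    x: Sequence[float],
    y: Sequence[float],
    lam: float = 1.0,
    conf_level: float = 0.95,
) -> DemingFit:
    """Errors-in-variables regression of y on x.

    ``lam`` is the ratio of y-error variance to x-error variance (lam = 1 is
    orthogonal regression).  The slope CI is a leave-one-out jackknife with a
    t quantile.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if lam <= 0:
        raise ValueError("lambda must be > 0")

    def _slope(xv: np.ndarray, yv: np.ndarray) -> float:
        sxx = np.var(xv, ddof=1)
        syy = np.var(yv, ddof=1)
        sxy = np.cov(xv, yv, ddof=1)[0, 1]
        if sxy == 0:
            raise ValueError("undefined Deming slope: zero covariance")
        d = syy - lam * sxx
        return (d + np.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)

    slope = _slope(x, y)
    intercept = float(y.mean() - slope * x.mean())
    loo = np.array([
        _slope(np.delete(x, i), np.delete(y, i)) for i in range(n)
    ])
    se = np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum())
    tq = stats.t.ppf(0.5 + conf_level / 2.0, n - 1)
    ci = (float(slope - tq * se), float(slope + tq * se))
    return DemingFit(float(slope), intercept, ci, lam, n)


def detect_shifts(
    intervals_a: Mapping[str, tuple[float, float]],
    intervals_b: Mapping[str, tuple[float, float]],
    means_a: Mapping[str, float],
    means_b: Mapping[str, float],
    family_of: Mapping[str, str],
) -> list[ShiftCall]:
    """Codons whose posterior intervals are disjoint between the two regions.

    Touching intervals (shared endpoint) count as overlap - no shift - which
    is the conservative reading.  Direction is sign(mean_B - mean_A).
    """
    calls = []
    for codon in intervals_a:
        lo_a, hi_a = intervals_a[codon]
        lo_b, hi_b = intervals_b[codon]
        if hi_a < lo_b or hi_b < lo_a:
            direction = int(np.sign(means_b[codon] - means_a[codon]))
            calls.append(ShiftCall(codon, family_of[codon], direction))
    return calls


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def binomial_fp_test(k_shifts: int, n_comparisons: int, p0: float = 0.05) -> float:
    """One-tailed exact binomial p-value P(X >= k) under X ~ Bin(n, p0)."""
    if not 0 <= k_shifts <= n_comparisons:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k_shifts - 1, n_comparisons, p0))


@dataclass
class ComparisonReport:
    """Full two-region comparison: per-codon table plus summary statistics."""

    region_a: str
    region_b: str
    table: pd.DataFrame  # per-codon rows
    deming: DemingFit
    spearman: float
    shifts: list[ShiftCall]
    n_comparisons: int
    binomial_p: float

    def summary(self) -> dict:
        return {
            "region_a": self.region_a,
            "region_b": self.region_b,
            "deming_slope": self.deming.slope,
            "deming_ci": list(self.deming.ci),
            "deming_lambda": self.deming.lam,
            "spearman_rho": self.spearman,
            "n_comparisons": self.n_comparisons,
            "n_shifts": len(self.shifts),
            "binomial_p": self.binomial_p,
        }

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compare_regions(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    favored: Mapping[str, str],
    table: CodonFamilyTable,
    level: float = 0.95,
    lam: float | None = None,
    region_a: str = "A",
    region_b: str = "B",
) -> ComparisonReport:
    """Build a :class:`ComparisonReport` from two rescaled region fits.

    The comparison covers the non-favored codons (one per family is pinned at
    0 by the rescaling), i.e. 40 comparisons under the standard serine-split
    table.  If ``lam`` is not given it defaults to the ratio of the two
    regions' mean posterior variances.
    """
    res_a = rescale_to_reference(samples_a, favored, table)
    res_b = rescale_to_reference(samples_b, favored, table)
    int_a = posterior_interval(res_a, level)
    int_b = posterior_interval(res_b, level)
    mean_a = res_a.posterior_mean()
    mean_b = res_b.posterior_mean()
    fam_of = table.family_of()

    compared = [
        c for fam in table.families for c in fam.codons
        if c != favored[fam.family_id]
    ]
    if lam is None:
        var_a = np.mean([res_a.column(c).var(ddof=1) for c in compared])
        var_b = np.mean([res_b.column(c).var(ddof=1) for c in compared])
        lam = float(var_b / var_a) if var_a > 0 else 1.0

    x = [mean_a[c] for c in compared]
    y = [mean_b[c] for c in compared]
    dem = deming_fit(x, y, lam=lam)
    rho = spearman_corr(x, y)
    calls = detect_shifts(
        {c: int_a[c] for c in compared},
        {c: int_b[c] for c in compared},
        mean_a, mean_b, fam_of,
    )
    p = binomial_fp_test(len(calls), len(compared))

    shifted = {c.codon for c in calls}
    rows = [
        {
            "codon": c,
            "family_id": fam_of[c],
            "mean_a": mean_a[c],
            "lo_a": int_a[c][0],
            "hi_a": int_a[c][1],
            "mean_b": mean_b[c],
            "lo_b": int_b[c][0],
            "hi_b": int_b[c][1],
            "shift": int(c in shifted),
            "direction": int(np.sign(mean_b[c] - mean_a[c])) if c in shifted else 0,
        }
        for c in compared
    ]
    return ComparisonReport(
        region_a=region_a,
        region_b=region_b,
        table=pd.DataFrame(rows),
        deming=dem,
        spearman=rho,
        shifts=calls,
        n_comparisons=len(compared),
        binomial_p=p,
    )


def plot_comparison(report: ComparisonReport, path) -> None:
    """Scatter of region-B vs region-A selection estimates with error bars,
    the y = x line, and the fitted Deming line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = report.table
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.errorbar(
        t["mean_a"], t["mean_b"],
        xerr=[t["mean_a"] - t["lo_a"], t["hi_a"] - t["mean_a"]],
        yerr=[t["mean_b"] - t["lo_b"], t["hi_b"] - t["mean_b"]],
        fmt="o", ms=3, lw=0.7, color="gray", ecolor="lightgray", zorder=2,
    )
    hits = t[t["shift"] == 1]
    ax.plot(hits["mean_a"], hits["mean_b"], "o", ms=4, color="crimson", zorder=3)
    lims = [
        min(t["lo_a"].min(), t["lo_b"].min()),
        max(t["hi_a"].max(), t["hi_b"].max()),
    ]
    grid = np.linspace(lims[0], lims[1], 10)
    ax.plot(grid, grid, "--", color="black", lw=0.8, label="y = x")
    ax.plot(
        grid, report.deming.intercept + report.deming.slope * grid,
        color="black", lw=1.2,
        label=(
            f"β = {report.deming.slope:.3f} "
            f"({report.deming.ci[0]:.3f}, {report.deming.ci[1]:.3f})"
        ),
    )
    ax.set_xlabel(f"Δη ({report.region_a})")
    ax.set_ylabel(f"Δη ({report.region_b})")
    ax.set_title(f"ρ_S = {report.spearman:.3f}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
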