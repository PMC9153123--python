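"""Bayesian estimation of the codon model by adaptive random-walk Metropolis.

Two fit modes:

* :func:`fit_full` — joint genome-wide fit of mutation bias, selection, and
  per-gene expression, with the mean-one identifiability constraint on phi
  enforced exactly after every sweep.
* :func:`fit_selection_only` — per-region fit of the selection coefficients
  with mutation bias and expression fixed at their genome-wide values;
  synonymous families are conditionally independent, so each family's block
  is sampled on its own.

A deviance trace (-2 log-likelihood per kept draw) is recorded for DIC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from codonshift.codon_core import (
    CodonCountMatrix,
    CodonFamilyTable,
    ExpressionVector,
    ParameterSet,
)

__all__ = [
    "McmcSettings",
    "PosteriorSamples",
    "DicResult",
    "fit_selection_only",
    "fit_full",
    "compute_dic",
    "compare_models",
    "posterior_interval",
]

logger = logging.getLogger(__name__)

_DIC_BANDS = (
    (2.0, "substantial"),
    (4.0, "strong"),
    (7.0, "less"),
    (10.0, "little"),
    (math.inf, "disregarded"),
)


@dataclass
class McmcSettings:
    """Chain configuration; defaults favor robustness over speed."""

    n_iterations: int = 20_000
    burn_in_fraction: float = 0.5
    thin: int = 10
    prior_sd: float = 10.0        # normal prior SD on delta_M / delta_eta
    phi_prior_sdlog: float = 1.0  # lognormal prior spread on phi
    adapt_interval: int = 50
    target_accept: tuple[float, float] = (0.2, 0.4)
    initial_scale: float = 0.2

    @property
    def n_burn(self) -> int:
        return int(self.n_iterations * self.burn_in_fraction)


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws with an aligned deviance trace."""

    param_names: list[str]
    draws: np.ndarray          # (n_draws, n_params)
    deviance: np.ndarray       # (n_draws,)
    seed: int
    settings: McmcSettings
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    loglik_fn: Callable[[np.ndarray], float] | None = None

    def __post_init__(self) -> None:
        if self.draws.shape[0] < 1:
            raise ValueError("need at least one draw")
        if self.deviance.shape[0] != self.draws.shape[0]:
            raise ValueError("deviance trace not aligned with draws")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def posterior_mean(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.mean()))

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def split_rhat_deviance(self) -> float:
        """Split-chain R-hat on the deviance trace (mixing diagnostic)."""
        d = self.deviance
        half = d.shape[0] // 2
        if half < 2:
            return float("nan")
        chains = np.stack([d[:half], d[half: 2 * half]])
        w = chains.var(axis=1, ddof=1).mean()
        b = half * chains.mean(axis=1).var(ddof=1)
        if w == 0:
            return 1.0
        return float(np.sqrt((w * (half - 1) / half + b / half) / w))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.param_names)
        df["deviance"] = self.deviance
        return df


@dataclass
class DicResult:
    """Deviance Information Criterion components (classic p_D variant)."""

    d_bar: float
    d_hat: float

    @property
    def p_d(self) -> float:
        return self.d_bar - self.d_hat

    @property
    def dic(self) -> float:
        return self.d_bar + self.p_d

    def __add__(self, other: "DicResult") -> "DicResult":
        # groups fitted independently: deviances (and hence DIC) add
        return DicResult(self.d_bar + other.d_bar, self.d_hat + other.d_hat)


class _ScalarAdapter:
    """Per-scalar proposal scale with windowed acceptance-rate adaptation."""

    def __init__(self, n: int, settings: McmcSettings):
        self.scale = np.full(n, settings.initial_scale)
        self.accept = np.zeros(n)
        self.tries = np.zeros(n)
        self.total_accept = np.zeros(n)
        self.total_tries = np.zeros(n)
        self.lo, self.hi = settings.target_accept

    def record(self, j: int, accepted: bool) -> None:
        self.tries[j] += 1
        self.total_tries[j] += 1
        if accepted:
            self.accept[j] += 1
            self.total_accept[j] += 1

    def adapt(self) -> None:
        with np.errstate(invalid="ignore"):
            rate = np.where(self.tries > 0, self.accept / np.maximum(self.tries, 1), 0.3)
        self.scale[rate < self.lo] /= 1.5
        self.scale[rate > self.hi] *= 1.5
        self.accept[:] = 0
        self.tries[:] = 0

    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.total_tries > 0,
                self.total_accept / np.maximum(self.total_tries, 1),
                np.nan,
            )


def _family_loglik(
    n_counts: np.ndarray,
    row_totals: np.ndarray,
    phi: np.ndarray,
    dm: np.ndarray,
    de: np.ndarray,
) -> float:
    """Multinomial log-likelihood of one family's counts given phi."""
    x = -(dm[None, :] + phi[:, None] * de[None, :])
    x = x - x.max(axis=1, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=1))
    return float((n_counts * x).sum() - row_totals @ lse)


def _log_normal_prior(value: float, sd: float) -> float:
    return -0.5 * (value / sd) ** 2


def fit_selection_only(
    group_counts: CodonCountMatrix,
    fixed_params: ParameterSet,
    fixed_phis: ExpressionVector,
    settings: McmcSettings | None = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Posterior draws of the free selection coefficients for one region.

    Mutation bias and per-gene expression are held fixed (their genome-wide
    estimates); each family's block is updated by per-scalar adaptive
    random-walk Metropolis.  Families with zero total counts fall back to
    prior draws, with a warning.
    """
    settings = settings or McmcSettings()
    table = group_counts.table
    if group_counts.gene_ids != fixed_phis.gene_ids:
        raise ValueError("group_counts and fixed_phis must cover the same genes")
    rng = np.random.default_rng(seed)
    phi_all = fixed_phis.phi

    fams = []
    param_names: list[str] = []
    warnings: list[str] = []
    for fam, sl in zip(table.families, table.family_slices().values()):
        n = group_counts.counts[:, sl].astype(float)
        keep = n.sum(axis=1) > 0
        dm = fixed_params.delta_M[sl]
        free = [j for j in range(fam.n_aa) if j != fam.reference_index]
        fam_state = {
            "id": fam.family_id,
            "codons": fam.codons,
            "counts": n[keep],
            "row_totals": n[keep].sum(axis=1),
            "phi": phi_all[keep],
            "dm": dm,
            "de": np.zeros(fam.n_aa),
            "free": free,
            "empty": n.sum() == 0,
            "offset": len(param_names),
            "ll": 0.0,
        }
        if fam_state["empty"]:
            warnings.append(
                f"family {fam.family_id} has zero counts; returning prior draws"
            )
        else:
            zero = [fam.codons[j] for j in free if n[:, j].sum() == 0]
            if zero:
                warnings.append(
                    f"family {fam.family_id}: zero-count codons {zero} "
                    "(prior-dominated)"
                )
            fam_state["ll"] = _family_loglik(
                fam_state["counts"], fam_state["row_totals"],
                fam_state["phi"], dm, fam_state["de"],
            )
        param_names.extend(fam.codons[j] for j in free)
        fams.append(fam_state)

    n_params = len(param_names)
    adapter = _ScalarAdapter(n_params, settings)
    n_burn = settings.n_burn
    kept_draws, kept_dev = [], []
    prior_sd = settings.prior_sd

    for it in range(settings.n_iterations):
        for fs in fams:
            if fs["empty"]:
                continue
            de = fs["de"]
            for k, j in enumerate(fs["free"]):
                p = fs["offset"] + k
                prop = de[j] + adapter.scale[p] * rng.standard_normal()
                de_new = de.copy()
                de_new[j] = prop
                ll_new = _family_loglik(
                    fs["counts"], fs["row_totals"], fs["phi"], fs["dm"], de_new
                )
                log_ratio = (
                    ll_new - fs["ll"]
                    + _log_normal_prior(prop, prior_sd)
                    - _log_normal_prior(de[j], prior_sd)
                )
                accepted = math.log(rng.random()) < log_ratio
                if accepted:
                    fs["de"] = de = de_new
                    fs["ll"] = ll_new
                adapter.record(p, accepted)
        if it < n_burn and (it + 1) % settings.adapt_interval == 0:
            adapter.adapt()
        if it >= n_burn and (it - n_burn) % settings.thin == 0:
            row = np.empty(n_params)
            total_ll = 0.0
            for fs in fams:
                if fs["empty"]:
                    for k, j in enumerate(fs["free"]):
                        row[fs["offset"] + k] = rng.normal(0.0, prior_sd)
                else:
                    for k, j in enumerate(fs["free"]):
                        row[fs["offset"] + k] = fs["de"][j]
                    total_ll += fs["ll"]
            kept_draws.append(row)
            kept_dev.append(-2.0 * total_ll)

    rates = adapter.rates()
    low = np.nanmin(rates) if n_params else float("nan")
    if np.isfinite(low) and low < 0.05:
        warnings.append(f"minimum acceptance rate {low:.3f} < 0.05: poor mixing")
        logger.warning("fit_selection_only: %s", warnings[-1])

    def loglik_at(params_vec: np.ndarray) -> float:
        total = 0.0
        for fs in fams:
            if fs["empty"]:
                continue
            de = np.zeros(len(fs["codons"]))
            for k, j in enumerate(fs["free"]):
                de[j] = params_vec[fs["offset"] + k]
            total += _family_loglik(
                fs["counts"], fs["row_totals"], fs["phi"], fs["dm"], de
            )
        return total

    return PosteriorSamples(
        param_names=param_names,
        draws=np.vstack(kept_draws),
        deviance=np.asarray(kept_dev),
        seed=seed,
        settings=settings,
        acceptance_rates=dict(zip(param_names, rates)),
        warnings=warnings,
        loglik_fn=loglik_at,
    )


def fit_full(
    genome_counts: CodonCountMatrix,
    settings: McmcSettings | None = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Joint fit of mutation bias, selection, and per-gene expression.

    Alternates per-scalar codon-parameter updates with a vectorized per-gene
    phi sweep (genes are conditionally independent given the codon
    parameters).  After every sweep phi is renormalized to mean 1 and the
    selection coefficients rescaled by the same factor, so E[phi] = 1 holds
    exactly in every draw.
    """
    settings = settings or McmcSettings()
    table = genome_counts.table
    n_genes = genome_counts.n_genes
    if n_genes < 2:
        raise ValueError("need at least 2 genes for a full fit")
    rng = np.random.default_rng(seed)

    slices = list(table.family_slices().values())
    fam_counts = [genome_counts.counts[:, sl].astype(float) for sl in slices]
    fam_rowtot = [n.sum(axis=1) for n in fam_counts]
    free_idx = [
        [j for j in range(f.n_aa) if j != f.reference_index]
        for f in table.families
    ]

    dm = [np.zeros(f.n_aa) for f in table.families]
    de = [np.zeros(f.n_aa) for f in table.families]
    log_phi = np.zeros(n_genes)

    def gene_logliks(log_phi_vec: np.ndarray) -> np.ndarray:
        phi = np.exp(log_phi_vec)
        out = np.zeros(n_genes)
        for n, rt, m, e in zip(fam_counts, fam_rowtot, dm, de):
            x = -(m[None, :] + phi[:, None] * e[None, :])
            x = x - x.max(axis=1, keepdims=True)
            lse = np.log(np.exp(x).sum(axis=1))
            out += (n * x).sum(axis=1) - rt * lse
        return out

    per_gene_ll = gene_logliks(log_phi)
    fam_ll = [
        _family_loglik(n, rt, np.exp(log_phi), m, e)
        for n, rt, m, e in zip(fam_counts, fam_rowtot, dm, de)
    ]

    codon_names = []
    for f, free in zip(table.families, free_idx):
        codon_names.extend(f"dM:{f.codons[j]}" for j in free)
        codon_names.extend(f"deta:{f.codons[j]}" for j in free)
    param_names = codon_names + [f"phi:{g}" for g in genome_counts.gene_ids]
    n_codon_params = len(codon_names)
    adapter = _ScalarAdapter(n_codon_params, settings)
    phi_scale = np.full(n_genes, settings.initial_scale)
    phi_accept = np.zeros(n_genes)
    phi_tries = 0
    prior_sd = settings.prior_sd
    s_phi = settings.phi_prior_sdlog
    mu_phi = -0.5 * s_phi**2

    def phi_logprior(lp: np.ndarray) -> np.ndarray:
        return -0.5 * ((lp - mu_phi) / s_phi) ** 2

    n_burn = settings.n_burn
    kept_draws, kept_dev = [], []
    warnings: list[str] = []

    for it in range(settings.n_iterations):
        phi = np.exp(log_phi)
        # codon-parameter updates, blocked per family
        p = 0
        for fi, (n, rt, free) in enumerate(zip(fam_counts, fam_rowtot, free_idx)):
            for which, vec in (("dM", dm[fi]), ("deta", de[fi])):
                for j in free:
                    prop_vec = vec.copy()
                    prop_vec[j] += adapter.scale[p] * rng.standard_normal()
                    if which == "dM":
                        ll_new = _family_loglik(n, rt, phi, prop_vec, de[fi])
                    else:
                        ll_new = _family_loglik(n, rt, phi, dm[fi], prop_vec)
                    log_ratio = (
                        ll_new - fam_ll[fi]
                        + _log_normal_prior(prop_vec[j], prior_sd)
                        - _log_normal_prior(vec[j], prior_sd)
                    )
                    accepted = math.log(rng.random()) < log_ratio
                    if accepted:
                        vec[j] = prop_vec[j]
                        fam_ll[fi] = ll_new
                    adapter.record(p, accepted)
                    p += 1
        # vectorized per-gene phi sweep
        per_gene_ll = gene_logliks(log_phi)
        prop_lp = log_phi + phi_scale * rng.standard_normal(n_genes)
        prop_ll = gene_logliks(prop_lp)
        log_ratio = (prop_ll - per_gene_ll) + phi_logprior(prop_lp) - phi_logprior(log_phi)
        accept = np.log(rng.random(n_genes)) < log_ratio
        log_phi = np.where(accept, prop_lp, log_phi)
        phi_accept += accept
        phi_tries += 1
        # enforce E[phi] = 1 exactly; rescale selection to compensate
        phi = np.exp(log_phi)
        m = phi.mean()
        log_phi -= math.log(m)
        for fi in range(len(de)):
            de[fi] *= m
        phi = np.exp(log_phi)
        fam_ll = [
            _family_loglik(n, rt, phi, mm, ee)
            for n, rt, mm, ee in zip(fam_counts, fam_rowtot, dm, de)
        ]
        if it < n_burn and (it + 1) % settings.adapt_interval == 0:
            adapter.adapt()
            rate = phi_accept / max(phi_tries, 1)
            phi_scale[rate < settings.target_accept[0]] /= 1.5
            phi_scale[rate > settings.target_accept[1]] *= 1.5
            phi_accept[:] = 0
            phi_tries = 0
        if it >= n_burn and (it - n_burn) % settings.thin == 0:
            row = []
            for fi, free in enumerate(free_idx):
                row.extend(dm[fi][j] for j in free)
                row.extend(de[fi][j] for j in free)
            row.extend(np.exp(log_phi))
            kept_draws.append(np.array(row))
            kept_dev.append(-2.0 * sum(fam_ll))

    rates = adapter.rates()
    low = np.nanmin(rates) if n_codon_params else float("nan")
    if np.isfinite(low) and low < 0.05:
        warnings.append(f"minimum acceptance rate {low:.3f} < 0.05: poor mixing")
        logger.warning("fit_full: %s", warnings[-1])

    def loglik_at(vec: np.ndarray) -> float:
        k = 0
        dm_l = [np.zeros(f.n_aa) for f in table.families]
        de_l = [np.zeros(f.n_aa) for f in table.families]
        for fi, free in enumerate(free_idx):
            for j in free:
                dm_l[fi][j] = vec[k]
                k += 1
            for j in free:
                de_l[fi][j] = vec[k]
                k += 1
        phi_v = np.asarray(vec[k:])
        total = 0.0
        for n, rt, mm, ee in zip(fam_counts, fam_rowtot, dm_l, de_l):
            total += _family_loglik(n, rt, phi_v, mm, ee)
        return total

    return PosteriorSamples(
        param_names=param_names,
        draws=np.vstack(kept_draws),
        deviance=np.asarray(kept_dev),
        seed=seed,
        settings=settings,
        acceptance_rates=dict(zip(codon_names, rates)),
        warnings=warnings,
        loglik_fn=loglik_at,
    )


def compute_dic(
    samples: PosteriorSamples,
    loglik_at: Callable[[np.ndarray], float] | None = None,
    variant: str = "p_d",
) -> DicResult:
    """DIC from a deviance trace: D_bar + p_D with p_D = D_bar - D_hat.

    D_hat is the deviance at the per-parameter posterior means.  The
    variance-based variant (p_V = var(D)/2) is available via
    ``variant="p_v"``.
    """
    if samples.n_draws < 2:
        raise ValueError("need at least 2 draws for DIC")
    loglik_at = loglik_at or samples.loglik_fn
    if loglik_at is None:
        raise ValueError("no log-likelihood function available")
    d_bar = float(samples.deviance.mean())
    if variant == "p_d":
        d_hat = -2.0 * loglik_at(samples.mean())
    elif variant == "p_v":
        p_v = float(samples.deviance.var(ddof=1)) / 2.0
        d_hat = d_bar - p_v
    else:
        raise ValueError(f"unknown DIC variant {variant!r}")
    return DicResult(d_bar, d_hat)


def compare_models(
    models: Sequence[tuple[str, DicResult]],
) -> pd.DataFrame:
    """Rank models by DIC; ΔDIC = DIC_i - DIC_best, annotated with the usual
    support bands (<2 substantial, 2-4 strong, 4-7 less, >=10 disregarded)."""
    if not models:
        raise ValueError("no models to compare")
    rows = [
        {
            "scheme": scheme_id,
            "d_bar": dic.d_bar,
            "p_d": dic.p_d,
            "dic": dic.dic,
        }
        for scheme_id, dic in models
    ]
    df = pd.DataFrame(rows).sort_values("dic", kind="stable").reset_index(drop=True)
    best = df["dic"].iloc[0]
    df["delta_dic"] = df["dic"] - best
    df["support"] = [
        next(band for cut, band in _DIC_BANDS if d < cut) for d in df["delta_dic"]
    ]
    return df


def posterior_interval(
    samples: PosteriorSamples, level: float = 0.95
) -> dict[str, tuple[float, float]]:
    """Equal-tailed posterior intervals (2.5%/97.5% quantiles at level 0.95)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(samples.draws, alpha, axis=0)
    hi = np.quantile(samples.draws, 1.0 - alpha, axis=0)
    return {
        name: (float(l), float(h))
        for name, l, h in zip(samples.param_names, lo, hi)
    }
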