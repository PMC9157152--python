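"""Genotype and trait simulation with controlled heterozygosity and h2.

Genotypes are drawn i.i.d. per cell with genotype probabilities
``((1-H)/2, H, (1-H)/2)`` for dosages (0, 1, 2): the counted-allele
frequency is 1/2 and the heterozygote excess/deficit is controlled
directly, so H = 0.5 corresponds to Hardy-Weinberg equilibrium at p = 1/2
and H = 0 to complete inbreeding (f = 1), via f = (0.5 - H)/0.5.  An
optional HWE variant draws per-marker frequencies p_j ~ Uniform(0.1, 0.9)
and dosages ~ Binomial(2, p_j) for robustness checks.

Traits are polygenic with every marker causal: effects u_j ~ N(0, 1),
genetic values g = Z u on the raw {0,1,2} dosages (centering only shifts g
by a constant absorbed by the intercept), and residual variance
``sigma_e^2 = s_g^2 (1 - h2) / h2`` where s_g^2 is the realized sample
variance of g, so the target heritability holds for the realized genetic
values of each replicate.

:func:`run_design_grid` executes design x GRM-method x replicate cells
(simulate, build GRM, REML fit, raw and ASV heritability) into a tidy
table, and :func:`summarize_bias_precision` reduces it to per-cell mean,
bias, SD and quartiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .asv import genomic_heritability_asv
from .grm import GenotypeMatrix, build_grm
from .lmm import PhenotypeVector, fit_reml

__all__ = [
    "SimulationDesign",
    "SimulatedTrait",
    "simulate_genotypes",
    "simulate_trait",
    "run_design_grid",
    "summarize_bias_precision",
    "paper_grid",
    "reduced_grid",
]

logger = logging.getLogger(__name__)

# offset separating the trait RNG stream from the genotype stream of a replicate
TRAIT_SEED_OFFSET = 1_000_000


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the simulation grid."""

    n: int
    m: int
    H: float
    h2: float
    reps: int = 1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3")
        if self.m < 1:
            raise ValueError("need m >= 1")
        if not 0.0 <= self.H < 1.0:
            raise ValueError("H must lie in [0, 1)")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if self.reps < 1:
            raise ValueError("need reps >= 1")


@dataclass(frozen=True)
class SimulatedTrait:
    """Marker effects, genetic values, residuals and phenotypes for one trait."""

    u: np.ndarray
    g: np.ndarray
    s_g2: float
    e: np.ndarray
    y: np.ndarray
    h2_true: float


def simulate_genotypes(
    n: int,
    m: int,
    H: float,
    seed: int,
    law: str = "fixed_het",
) -> GenotypeMatrix:
    """Simulate an n x m dosage matrix with target mean heterozygosity H.

    ``law="fixed_het"`` (default): i.i.d. genotypes with probabilities
    ((1-H)/2, H, (1-H)/2) for dosages (0, 1, 2).  ``law="hwe_uniform"``:
    per-marker p_j ~ Uniform(0.1, 0.9), dosages ~ Binomial(2, p_j); H is
    ignored.  Reproducible given ``seed``.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 and m >= 1")
    if not 0.0 <= H < 1.0:
        raise ValueError("H must lie in [0, 1); H = 1 is degenerate (Kbar = 0)")
    rng = np.random.default_rng(seed)
    if law == "fixed_het":
        probs = [(1.0 - H) / 2.0, H, (1.0 - H) / 2.0]
        dosages = rng.choice([0, 1, 2], size=(n, m), p=probs)
    elif law == "hwe_uniform":
        p = rng.uniform(0.1, 0.9, size=m)
        dosages = rng.binomial(2, p[None, :], size=(n, m))
    else:
        raise ValueError(f"unknown genotype law {law!r}")
    return GenotypeMatrix.from_array(dosages.astype(float))


def simulate_trait(G: GenotypeMatrix, h2: float, seed: int) -> SimulatedTrait:
    """Simulate a fully polygenic trait with target genomic heritability h2.

    u_j ~ N(0,1); g = Z u on raw dosages; sigma_e^2 = s_g^2 (1-h2)/h2 with
    s_g^2 the sample variance of g; y = g + e.  h2 = 1 gives a noiseless
    trait.  Raises on h2 outside (0, 1] or a monomorphic genotype matrix
    (s_g^2 = 0).
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(G.m)
    g = G.dosages @ u
    s_g2 = float(np.var(g, ddof=1))
    if s_g2 == 0.0:
        raise ValueError("genetic values have zero variance (monomorphic genotypes)")
    sigma_e2 = s_g2 * (1.0 - h2) / h2
    e = rng.normal(0.0, np.sqrt(sigma_e2), G.n) if sigma_e2 > 0 else np.zeros(G.n)
    return SimulatedTrait(u=u, g=g, s_g2=s_g2, e=e, y=g + e, h2_true=h2)


def paper_grid(
    reps: int = 1000, m: int = 5000, base_seed: int = 0
) -> list[SimulationDesign]:
    """The full 36-cell grid: H x h2 x n = {0,.25,.5,.75} x {.2,.5,.8} x {250,500,1000}."""
    return [
        SimulationDesign(n=n, m=m, H=H, h2=h2, reps=reps, base_seed=base_seed)
        for H in (0.0, 0.25, 0.5, 0.75)
        for h2 in (0.2, 0.5, 0.8)
        for n in (250, 500, 1000)
    ]


def reduced_grid(
    reps: int = 200, n: int = 250, m: int = 1000, base_seed: int = 0
) -> list[SimulationDesign]:
    """Desk-scale 12-cell grid (single n) over H x h2."""
    return [
        SimulationDesign(n=n, m=m, H=H, h2=h2, reps=reps, base_seed=base_seed)
        for H in (0.0, 0.25, 0.5, 0.75)
        for h2 in (0.2, 0.5, 0.8)
    ]


def run_design_grid(
    designs: Iterable[SimulationDesign],
    methods: Sequence[str] = ("asv",),
    progress: bool = False,
) -> pd.DataFrame:
    """Run simulate -> GRM -> REML -> heritability over all grid cells.

    Returns a tidy frame with one row per design x method x replicate:
    design fields, method, rep, seed, sigma_g2, sigma_e2, h2_raw, h2_asv.
    Per-replicate seed = base_seed + rep (genotypes; the trait stream adds
    ``TRAIT_SEED_OFFSET``).  Replicate failures are logged and skipped; the
    failure count is stored in ``df.attrs["n_failures"]``.
    """
    rows = []
    n_failures = 0
    for design in designs:
        for rep in range(design.reps):
            seed = design.base_seed + rep
            try:
                G = simulate_genotypes(design.n, design.m, design.H, seed=seed)
                trait = simulate_trait(G, design.h2, seed=seed + TRAIT_SEED_OFFSET)
                y = PhenotypeVector(trait.y, G.entry_ids)
            except Exception:
                logger.exception("replicate %d of design %s failed in simulation", rep, design)
                n_failures += len(methods)
                continue
            for method in methods:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        K = build_grm(G, method)
                        vc = fit_reml(y, K)
                    est = genomic_heritability_asv(K, vc.sigma_g2, vc.sigma_e2)
                except Exception:
                    logger.exception(
                        "replicate %d of design %s failed for method %s", rep, design, method
                    )
                    n_failures += 1
                    continue
                rows.append(
                    {
                        "n": design.n,
                        "m": design.m,
                        "H": design.H,
                        "h2_true": design.h2,
                        "method": method,
                        "rep": rep,
                        "seed": seed,
                        "sigma_g2": vc.sigma_g2,
                        "sigma_e2": vc.sigma_e2,
                        "h2_raw": est.h2_raw,
                        "h2_asv": est.h2_asv,
                    }
                )
            if progress and (rep + 1) % 50 == 0:
                logger.info("design %s: %d/%d replicates done", design, rep + 1, design.reps)
    df = pd.DataFrame(rows)
    df.attrs["n_failures"] = n_failures
    if n_failures:
        logger.warning("%d replicate fits failed and were skipped", n_failures)
    return df


def summarize_bias_precision(results: pd.DataFrame) -> pd.DataFrame:
    """Per design x method summary: mean, bias, SD and quartiles of h2 estimates.

    Both the raw and the ASV-adjusted heritability columns are summarized.
    """
    if results.empty:
        raise ValueError("results table is empty")
    keys = ["n", "m", "H", "h2_true", "method"]
    out = []
    for vals, sub in results.groupby(keys):
        row = dict(zip(keys, vals))
        row["reps"] = len(sub)
        for col in ("h2_raw", "h2_asv"):
            est = sub[col].to_numpy()
            row[f"mean_{col}"] = est.mean()
            row[f"bias_{col}"] = est.mean() - row["h2_true"]
            row[f"sd_{col}"] = est.std(ddof=1) if len(est) > 1 else 0.0
            row[f"q25_{col}"] = np.quantile(est, 0.25)
            row[f"q50_{col}"] = np.quantile(est, 0.50)
            row[f"q75_{col}"] = np.quantile(est, 0.75)
        out.append(row)
    return pd.DataFrame(out).sort_values(keys).reset_index(drop=True)
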