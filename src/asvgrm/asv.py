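"""Average-semivariance (ASV) variance decomposition and heritability.

The ASV of a random vector is half the average pairwise variance of
differences between entries, equivalently the expected sample variance.
For the single-kernel LMM with V = K sigma_g^2 + I sigma_e^2 the ASV
phenotypic variance is ``(n-1)^-1 tr(V P)`` (P the centering projector),
which splits into a genomic part ``(n-1)^-1 tr(K P) sigma_g^2`` and a
residual part that is just ``sigma_e^2``.  Dividing gives the ASV
heritability; with the ASV-scaled GRM the trace factor is 1 and raw REML
components can be plugged into the plain ratio unchanged.  For any other
GRM, :func:`posthoc_adjust` multiplies the fitted genomic variance by the
trace factor, which reproduces the direct ASV fit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grm import RelationshipMatrix, asv_scaling_factor
from .lmm import VarianceComponents

__all__ = [
    "ASVEstimates",
    "asv_genomic_variance",
    "asv_residual_variance",
    "genomic_heritability",
    "genomic_heritability_asv",
    "posthoc_adjust",
]


@dataclass(frozen=True)
class ASVEstimates:
    """ASV variance decomposition and heritability for one fitted model.

    ``h2_raw`` is the unadjusted ratio sigma_g^2/(sigma_g^2 + sigma_e^2)
    reported beside ``h2_asv`` so the GRM-scaling bias is visible;
    ``theta_y = theta_g + theta_e`` holds exactly by construction.
    """

    theta_g: float
    theta_e: float
    theta_y: float
    scaling_factor: float
    h2_asv: float
    h2_raw: float
    grm_method: str | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.theta_y != self.theta_g + self.theta_e:
            raise ValueError("theta_y must equal theta_g + theta_e exactly")

    def to_dict(self) -> dict:
        return {
            "theta_g": self.theta_g,
            "theta_e": self.theta_e,
            "theta_y": self.theta_y,
            "scaling_factor": self.scaling_factor,
            "h2_asv": self.h2_asv,
            "h2_raw": self.h2_raw,
            "grm_method": self.grm_method,
            "n": self.n,
        }


def asv_genomic_variance(K: RelationshipMatrix, sigma_g2: float) -> float:
    """ASV genomic variance ``(n-1)^-1 tr(K P) sigma_g^2``."""
    if sigma_g2 < 0:
        raise ValueError("sigma_g2 must be non-negative")
    return asv_scaling_factor(K) * sigma_g2


def asv_residual_variance(sigma_e2: float, n: int) -> float:
    """ASV residual variance; equals sigma_e2 since (n-1)^-1 tr(P) = 1."""
    if n < 2:
        raise ValueError("need n >= 2")
    return float(sigma_e2)


def genomic_heritability(sigma_g2: float, sigma_e2: float) -> float:
    """Plain genomic heritability sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
    total = sigma_g2 + sigma_e2
    if total <= 0:
        raise ValueError("sigma_g2 + sigma_e2 must be positive")
    return sigma_g2 / total


def genomic_heritability_asv(
    K: RelationshipMatrix, sigma_g2: float, sigma_e2: float
) -> ASVEstimates:
    """ASV heritability from raw variance components fitted with GRM ``K``.

    ``h2_asv = c sigma_g^2 / (c sigma_g^2 + sigma_e^2)`` with the trace
    factor ``c = (n-1)^-1 tr(K P)``; for the ASV matrix c = 1 and
    ``h2_asv == h2_raw``.
    """
    n = K.n
    factor = asv_scaling_factor(K)
    theta_g = factor * sigma_g2
    theta_e = asv_residual_variance(sigma_e2, n)
    theta_y = theta_g + theta_e
    if theta_y <= 0:
        raise ValueError("total ASV variance must be positive")
    return ASVEstimates(
        theta_g=theta_g,
        theta_e=theta_e,
        theta_y=theta_y,
        scaling_factor=factor,
        h2_asv=theta_g / theta_y,
        h2_raw=genomic_heritability(sigma_g2, sigma_e2),
        grm_method=K.method,
        n=n,
    )


def posthoc_adjust(K: RelationshipMatrix, vc: VarianceComponents) -> ASVEstimates:
    """Trace-adjust REML components from any GRM to the ASV scale.

    Equivalent to refitting with the ASV matrix directly (dual-path
    equivalence).  ``vc`` must carry the same GRM method tag as ``K``.
    """
    if vc.grm_method is not None and vc.grm_method != K.method:
        raise ValueError(
            f"variance components were fitted with GRM {vc.grm_method!r}, "
            f"not {K.method!r}"
        )
    return genomic_heritability_asv(K, vc.sigma_g2, vc.sigma_e2)
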