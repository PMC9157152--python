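"""Genomic relationship matrices (GRMs) from SNP dosage data.

A GRM ``K`` summarises realized genomic relatedness between entries from a
dosage matrix ``Z`` (n entries x m markers, counts of a designated allele in
{0, 1, 2}) and enters the mixed model as the covariance kernel of genetic
values, ``g ~ N(0, K sigma_g^2)``.  The scaling and centering applied to
``Z`` differ between published constructions, and because ``sigma_g^2`` is a
scalar multiplying ``K``, that choice propagates directly into variance
component estimates.

Seven constructions are provided:

``asv``
    Average-semivariance matrix ``K_ASV = Kbar / ((n-1)^-1 tr(Kbar))`` with
    ``Kbar = Zbar Zbar'`` and ``Zbar`` the column-mean-centered dosages.
    By construction ``tr(K_ASV) = n - 1`` and every row sums to zero, so
    REML variance components can be read as the sample (semi)variance of
    genetic values in the observed population.
``gn``
    Normalized matrix ``K_GN = Kbar / (n^-1 tr(Kbar))``; identical to
    ``asv`` up to the factor ``n/(n-1)``.
``vr``
    VanRaden's matrix ``Zbar Zbar' / (2 sum_j p_j (1-p_j))`` with ``Zbar``
    centered on ``2 p_j``.  With observed allele frequencies it is an exact
    scalar multiple of ``K_ASV``.
``ej``
    Endelman-Jannink shrinkage matrix: the marker covariance is shrunk
    toward its mean diagonal with intensity ``delta = (n/m) / CV^2`` and
    renormalized like VanRaden's matrix; ``delta = 0`` recovers ``vr``.
``yang``
    Yang's (GCTA) matrix with per-marker standardization and a separate
    diagonal formula.
``ab``
    Astle-Balding matrix: per-marker standardized cross-products averaged
    over markers (off-diagonals coincide with Yang's).
``ibs``
    Identity-by-state, the only construction independent of allele
    frequencies: ``(2m)^-1 sum_j (z_j - 1)(z_j - 1)' + 1/2``.

All constructions accept the same :class:`GenotypeMatrix`; the dispatcher
:func:`build_grm` selects by tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GRM_METHODS",
    "DegenerateRelatednessError",
    "GenotypeMatrix",
    "AlleleFrequencies",
    "RelationshipMatrix",
    "allele_frequencies",
    "observed_heterozygosity",
    "center_markers",
    "kbar",
    "asv_scaling_factor",
    "grm_asv",
    "grm_gn",
    "grm_vanraden",
    "grm_yang",
    "grm_astle_balding",
    "grm_endelman_jannink",
    "grm_ibs",
    "build_grm",
]

#: Valid method tags, also used by the CLI ``--method`` flag.
GRM_METHODS = ("asv", "gn", "vr", "ej", "yang", "ab", "ibs")


class DegenerateRelatednessError(ValueError):
    """All markers monomorphic (or otherwise zero realized relatedness)."""


def _default_labels(prefix: str, k: int) -> tuple[str, ...]:
    width = max(1, len(str(k)))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(k))


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x m allele-count (dosage) matrix with entry and marker labels.

    Dosages are counts in {0, 1, 2} of an arbitrary designated allele per
    marker.  Missing calls are allowed only on ingestion and are mean-imputed
    per marker (see :meth:`from_array`); ``n_imputed`` records how many.
    """

    dosages: np.ndarray
    entry_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    n_imputed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        if d.ndim != 2:
            raise ValueError("dosages must be a 2-D (entries x markers) array")
        n, m = d.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 entries and m >= 1 markers, got {n} x {m}")
        if len(self.entry_ids) != n or len(self.marker_ids) != m:
            raise ValueError("label lengths do not match dosage shape")
        if len(set(self.entry_ids)) != n:
            raise ValueError("entry_ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker_ids are not unique")
        if not np.all(np.isfinite(d)):
            raise ValueError("dosages contain non-finite values after ingestion")
        if d.min() < 0.0 or d.max() > 2.0:
            raise ValueError("dosages must lie in [0, 2]")
        if self.n_imputed == 0 and not np.all(np.isin(d, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be integers in {0, 1, 2}")

    @classmethod
    def from_array(
        cls,
        dosages: np.ndarray,
        entry_ids: Sequence[str] | None = None,
        marker_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Build from an array; NaN cells are mean-imputed per marker."""
        d = np.array(dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D")
        missing = ~np.isfinite(d)
        n_imputed = int(missing.sum())
        if n_imputed:
            col_mean = np.nanmean(np.where(missing, np.nan, d), axis=0)
            # fully-missing column: fall back to 0 (monomorphic reference)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            d = np.where(missing, col_mean[None, :], d)
        n, m = d.shape
        return cls(
            dosages=d,
            entry_ids=tuple(entry_ids) if entry_ids is not None else _default_labels("E", n),
            marker_ids=tuple(marker_ids) if marker_ids is not None else _default_labels("M", m),
            n_imputed=n_imputed,
        )

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


@dataclass(frozen=True)
class AlleleFrequencies:
    """Per-marker frequency of the counted allele, in [0, 1].

    ``source`` is ``"observed"`` when computed as half the column mean of the
    dosages, ``"supplied"`` when provided externally (e.g. from a reference
    population).  Frequencies are of the counted allele, not folded to MAF:
    folding changes no centered quantity.
    """

    p: np.ndarray
    source: str = "observed"

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.ndim != 1:
            raise ValueError("p must be a 1-D vector")
        if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.source not in ("observed", "supplied"):
            raise ValueError(f"unknown source tag {self.source!r}")


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric n x n labeled relationship matrix with a method tag."""

    values: np.ndarray
    entry_ids: tuple[str, ...]
    method: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if len(self.entry_ids) != v.shape[0]:
            raise ValueError("entry_ids length does not match matrix order")
        scale = np.abs(v).max()
        if scale > 0 and np.abs(v - v.T).max() > 1e-10 * scale:
            raise ValueError("relationship matrix is not symmetric")
        object.__setattr__(self, "values", (v + v.T) / 2.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        """Extract the principal submatrix for the given entry ids."""
        idx = [self.entry_ids.index(i) for i in ids]
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)], tuple(ids), self.method, dict(self.meta)
        )


# ---------------------------------------------------------------------------
# basic marker statistics


def allele_frequencies(G: GenotypeMatrix) -> AlleleFrequencies:
    """Observed frequency of the counted allele: half the column mean."""
    return AlleleFrequencies(G.dosages.mean(axis=0) / 2.0, source="observed")


def observed_heterozygosity(G: GenotypeMatrix) -> float:
    """Fraction of all n*m dosage calls that are heterozygous (dosage 1)."""
    return float(np.mean(G.dosages == 1.0))


def center_markers(G: GenotypeMatrix) -> np.ndarray:
    """Column-mean-centered marker matrix Zbar = P Z.

    Column-mean subtraction is used instead of materializing the n x n
    centering projector P = I - 11'/n; the two are identical and this is
    O(nm).
    """
    Z = G.dosages
    return Z - Z.mean(axis=0, keepdims=True)


def kbar(G: GenotypeMatrix) -> RelationshipMatrix:
    """Unscaled cross-product matrix Kbar = Zbar Zbar'; rows sum to zero."""
    Zc = center_markers(G)
    return RelationshipMatrix(Zc @ Zc.T, G.entry_ids, method="custom", meta={"kind": "kbar"})


def asv_scaling_factor(K: RelationshipMatrix | np.ndarray) -> float:
    """Trace-scaling factor ``(n-1)^-1 tr(K P)`` for any GRM.

    ``tr(K P) = tr(K) - mean row sum``, which removes additive constants
    (e.g. the +1/2 of the IBS matrix) so uncentered GRMs are handled
    correctly.  Raises :class:`DegenerateRelatednessError` when the factor
    is not positive (e.g. Kbar = 0).
    """
    V = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)
    n = V.shape[0]
    if n < 2:
        raise ValueError("need n >= 2")
    factor = (np.trace(V) - V.sum() / n) / (n - 1)
    if factor <= 0.0:
        raise DegenerateRelatednessError(
            f"scaling factor (n-1)^-1 tr(KP) = {factor:.3g} is not positive; "
            "relatedness is degenerate (all markers monomorphic?)"
        )
    return float(factor)


# ---------------------------------------------------------------------------
# the seven GRMs


def grm_asv(G: GenotypeMatrix) -> RelationshipMatrix:
    """Average-semivariance GRM: Kbar scaled so that tr(K_ASV) = n - 1.

    With this scaling the REML genomic variance is the average semivariance
    (expected sample variance) of genetic values in the observed population
    and needs no post-hoc adjustment.
    """
    Kb = kbar(G)
    factor = asv_scaling_factor(Kb)
    return RelationshipMatrix(
        Kb.values / factor, G.entry_ids, method="asv", meta={"scaling_factor": factor}
    )


def grm_gn(G: GenotypeMatrix) -> RelationshipMatrix:
    """Normalized GRM: Kbar / (n^-1 tr(Kbar)); tr(K_GN) = n.

    Differs from the ASV matrix only by the factor n/(n-1) (population vs
    sample variance denominator).
    """
    Kb = kbar(G)
    n = G.n
    tr = np.trace(Kb.values)
    if tr <= 0.0:
        raise DegenerateRelatednessError("tr(Kbar) is not positive")
    return RelationshipMatrix(Kb.values / (tr / n), G.entry_ids, method="gn")


def _resolve_freqs(G: GenotypeMatrix, p: AlleleFrequencies | None) -> AlleleFrequencies:
    if p is None:
        return allele_frequencies(G)
    if len(p.p) != G.m:
        raise ValueError("allele frequency vector length does not match marker count")
    return p


def grm_vanraden(
    G: GenotypeMatrix, p: AlleleFrequencies | None = None
) -> RelationshipMatrix:
    """VanRaden GRM: (Z - 2p)(Z - 2p)' / (2 sum_j p_j(1-p_j)).

    Monomorphic markers (p_j in {0, 1}) contribute nothing to either the
    numerator (for observed p) or the denominator and are skipped with a
    warning.  With observed frequencies the result is an exact scalar
    multiple of the ASV matrix.
    """
    p = _resolve_freqs(G, p)
    het = p.p * (1.0 - p.p)
    keep = het > 0.0
    if not keep.any():
        raise DegenerateRelatednessError("all markers are monomorphic")
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} monomorphic marker(s) skipped in VanRaden GRM",
            stacklevel=2,
        )
    Zc = G.dosages[:, keep] - 2.0 * p.p[None, keep]
    denom = 2.0 * het[keep].sum()
    return RelationshipMatrix(
        Zc @ Zc.T / denom, G.entry_ids, method="vr", meta={"freq_source": p.source}
    )


def grm_yang(G: GenotypeMatrix, p: AlleleFrequencies | None = None) -> RelationshipMatrix:
    """Yang (GCTA) GRM with separately standardized diagonal.

    Off-diagonal (i != k): m^-1 sum_j (z_ji - 2p_j)(z_jk - 2p_j) / (2p_j(1-p_j));
    diagonal: 1 + m^-1 sum_j (z_ji^2 - (1 + 2p_j) z_ji + 2 p_j^2) / (2p_j(1-p_j)).
    Markers with p_j in {0, 1} would divide by zero and are excluded with a
    warning.  The modified diagonal means the matrix need not be PSD.
    """
    p = _resolve_freqs(G, p)
    het = 2.0 * p.p * (1.0 - p.p)
    keep = het > 0.0
    if not keep.any():
        raise DegenerateRelatednessError("all markers are monomorphic")
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} monomorphic marker(s) excluded from Yang GRM",
            stacklevel=2,
        )
    Z = G.dosages[:, keep]
    pk, hk = p.p[keep], het[keep]
    mk = Z.shape[1]
    Zs = (Z - 2.0 * pk[None, :]) / np.sqrt(hk)[None, :]
    K = Zs @ Zs.T / mk
    diag = 1.0 + ((Z * Z - (1.0 + 2.0 * pk[None, :]) * Z + 2.0 * pk[None, :] ** 2) / hk[None, :]).sum(axis=1) / mk
    np.fill_diagonal(K, diag)
    return RelationshipMatrix(K, G.entry_ids, method="yang", meta={"m_used": mk})


def grm_astle_balding(
    G: GenotypeMatrix, p: AlleleFrequencies | None = None
) -> RelationshipMatrix:
    """Astle-Balding GRM: m^-1 sum_j (z_j - 2p_j 1)(z_j - 2p_j 1)' / (2p_j(1-p_j)).

    Per-marker standardized cross-products averaged over markers; the
    off-diagonals equal Yang's.  Monomorphic markers are excluded as in
    :func:`grm_yang`.
    """
    p = _resolve_freqs(G, p)
    het = 2.0 * p.p * (1.0 - p.p)
    keep = het > 0.0
    if not keep.any():
        raise DegenerateRelatednessError("all markers are monomorphic")
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} monomorphic marker(s) excluded from Astle-Balding GRM",
            stacklevel=2,
        )
    Z = G.dosages[:, keep]
    Zs = (Z - 2.0 * p.p[keep][None, :]) / np.sqrt(het[keep])[None, :]
    return RelationshipMatrix(
        Zs @ Zs.T / Z.shape[1], G.entry_ids, method="ab", meta={"m_used": int(Z.shape[1])}
    )


def grm_endelman_jannink(
    G: GenotypeMatrix, force_delta: float | None = None
) -> tuple[RelationshipMatrix, float]:
    """Endelman-Jannink shrinkage GRM; returns (matrix, delta).

    The marker covariance about its column-mean outer product,
    ``S = m^-1 Zbar Zbar' - zbar zbar'`` with ``zbar`` the mean centered
    marker column, is shrunk toward ``<S_ii> I`` with intensity
    ``delta = (n/m) / CV^2`` (CV of the informative eigenvalues of S,
    excluding the structural null eigenvalue induced by centering), clamped
    to [0, 1].  The shrunken matrix plus the re-added mean outer product is
    normalized by ``2 <p_j(1-p_j)>``.  With ``delta = 0`` the result equals
    the VanRaden GRM with observed frequencies.
    """
    n, m = G.n, G.m
    if m < 2:
        raise ValueError("Endelman-Jannink shrinkage needs m >= 2 markers")
    p = allele_frequencies(G)
    het_mean = 2.0 * np.mean(p.p * (1.0 - p.p))
    if het_mean <= 0.0:
        raise DegenerateRelatednessError("all markers are monomorphic")
    Zc = center_markers(G)
    zbar = Zc.mean(axis=1)
    S = Zc @ Zc.T / m - np.outer(zbar, zbar)
    if force_delta is not None:
        delta = float(force_delta)
        if not 0.0 <= delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
    else:
        eigs = np.linalg.eigvalsh((S + S.T) / 2.0)
        eigs = eigs[1:]  # drop the structural null eigenvalue (S 1 = 0)
        mean_eig = eigs.mean()
        var_eig = eigs.var(ddof=1) if eigs.size > 1 else 0.0
        if mean_eig <= 0.0 or var_eig <= 0.0:
            warnings.warn(
                "degenerate eigenvalue dispersion of S; shrinkage delta clamped to 1",
                stacklevel=2,
            )
            delta = 1.0
        else:
            cv2 = var_eig / mean_eig**2
            delta = min(1.0, (n / m) / cv2)
    K = (delta * np.mean(np.diag(S)) * np.eye(n) + (1.0 - delta) * S + np.outer(zbar, zbar)) / het_mean
    return (
        RelationshipMatrix(K, G.entry_ids, method="ej", meta={"delta": delta}),
        delta,
    )


def grm_ibs(G: GenotypeMatrix) -> RelationshipMatrix:
    """Identity-by-state GRM: (2m)^-1 sum_j (z_j - 1)(z_j - 1)' + 1/2.

    Assumes the {0, 1, 2} dosage convention (not shift-invariant); all
    elements lie in [0, 1] and no allele-frequency scaling is applied.
    """
    Zc = G.dosages - 1.0
    K = Zc @ Zc.T / (2.0 * G.m) + 0.5
    return RelationshipMatrix(K, G.entry_ids, method="ibs")


_BUILDERS = {
    "asv": grm_asv,
    "gn": grm_gn,
    "vr": grm_vanraden,
    "yang": grm_yang,
    "ab": grm_astle_balding,
    "ibs": grm_ibs,
}


def build_grm(
    G: GenotypeMatrix, method: str, p: AlleleFrequencies | None = None
) -> RelationshipMatrix:
    """Construct a GRM by method tag (one of asv|gn|vr|ej|yang|ab|ibs)."""
    method = method.lower()
    if method == "ej":
        K, _ = grm_endelman_jannink(G)
        return K
    if method not in _BUILDERS:
        raise ValueError(f"unknown GRM method {method!r}; choose from {GRM_METHODS}")
    if method in ("vr", "yang", "ab"):
        return _BUILDERS[method](G, p)
    return _BUILDERS[method](G)
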