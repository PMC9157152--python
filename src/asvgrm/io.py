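"""Readers and writers for genotypes, phenotypes, GRMs, and results.

The canonical interchange format is plain TSV: genotype tables carry a
header row of marker ids and a first column of entry ids with dosage cells
in {0, 1, 2, NA}; phenotype tables are two columns (entry_id, value);
GRMs are stored as full square matrices with entry ids on both margins.
PLINK ``.raw`` exports and VCF (GT-derived dosages, biallelic records only)
are supported as convenience readers.  Readers reject malformed cells,
naming the offending row/column, rather than silently coercing.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .grm import GenotypeMatrix, RelationshipMatrix
from .lmm import PhenotypeVector
from .simulate import SimulationDesign

__all__ = [
    "ParseError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_grm_tsv",
    "write_grm_tsv",
    "write_grm_gcta",
    "read_designs",
    "write_results_tsv",
]

logger = logging.getLogger(__name__)

_VALID_CELLS = {"0", "1", "2"}
_NA_CELLS = {"NA", "NAN", "", "."}


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


def _parse_dosage_cells(values: np.ndarray, entry_ids, marker_ids, path) -> np.ndarray:
    """str cell array -> float dosages with NaN for missing; strict otherwise."""
    out = np.empty(values.shape, dtype=float)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            cell = str(values[i, j]).strip()
            if cell in _VALID_CELLS:
                out[i, j] = float(cell)
            elif cell.upper() in _NA_CELLS or cell.lower() == "nan":
                out[i, j] = np.nan
            else:
                raise ParseError(
                    f"{path}: non-dosage cell {cell!r} at entry {entry_ids[i]!r} "
                    f"(row {i + 2}), marker {marker_ids[j]!r} (column {j + 2})"
                )
    return out


def _infer_format(path: Path) -> str:
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".raw"):
        return "plink_raw"
    if ".vcf" in suffixes:
        return "vcf"
    return "tsv"


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a dosage matrix from TSV, PLINK .raw, or VCF.

    Missing calls are mean-imputed per marker; the imputation count is
    recorded on the returned :class:`GenotypeMatrix` and logged.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        G = _read_genotypes_tsv(path)
    elif fmt == "plink_raw":
        G = _read_genotypes_plink_raw(path)
    elif fmt == "vcf":
        G = _read_genotypes_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if G.n_imputed:
        logger.info("%s: mean-imputed %d missing dosage(s)", path, G.n_imputed)
    return G


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    entry_ids = [str(e) for e in df.index]
    marker_ids = [str(c) for c in df.columns]
    if len(set(entry_ids)) != len(entry_ids):
        raise ParseError(f"{path}: duplicate entry ids")
    if len(set(marker_ids)) != len(marker_ids):
        raise ParseError(f"{path}: duplicate marker ids")
    dosages = _parse_dosage_cells(df.to_numpy(), entry_ids, marker_ids, path)
    return GenotypeMatrix.from_array(dosages, entry_ids, marker_ids)


_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_genotypes_plink_raw(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing_meta = [c for c in _PLINK_META if c not in df.columns]
    if missing_meta:
        raise ParseError(f"{path}: not a PLINK .raw file (missing columns {missing_meta})")
    entry_ids = [str(e) for e in df["IID"]]
    if len(set(entry_ids)) != len(entry_ids):
        raise ParseError(f"{path}: duplicate IIDs")
    marker_cols = [c for c in df.columns if c not in _PLINK_META]
    if not marker_cols:
        raise ParseError(f"{path}: no marker columns")
    dosages = _parse_dosage_cells(
        df[marker_cols].to_numpy(), entry_ids, marker_cols, path
    )
    return GenotypeMatrix.from_array(dosages, entry_ids, marker_cols)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF support requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    entry_ids = [str(s) for s in vcf.samples]
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos = np.where(gt == 2, np.nan, dos)
        cols.append(dos)
        marker_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multiallelic record(s)", stacklevel=2)
    if not cols:
        raise ParseError(f"{path}: no usable biallelic records")
    return GenotypeMatrix.from_array(np.column_stack(cols), entry_ids, marker_ids)


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage matrix as TSV (integral cells where possible)."""
    df = pd.DataFrame(G.dosages, index=list(G.entry_ids), columns=list(G.marker_ids))
    integral = np.all(G.dosages == np.round(G.dosages))
    df.to_csv(path, sep="\t", float_format="%g" if integral else "%.10g")


def read_phenotypes(path: str | Path) -> PhenotypeVector:
    """Read a two-column (entry_id, value) TSV with a header row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected exactly two columns (entry_id, value)")
    ids = [str(e) for e in df.iloc[:, 0]]
    vals = np.empty(len(ids), dtype=float)
    for i, raw in enumerate(df.iloc[:, 1]):
        try:
            vals[i] = float(raw)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric phenotype {raw!r} for entry {ids[i]!r} (row {i + 2})"
            ) from None
    return PhenotypeVector(vals, tuple(ids))


def write_phenotypes(y: PhenotypeVector, path: str | Path) -> None:
    pd.DataFrame({"entry_id": list(y.entry_ids), "value": y.values}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_grm_tsv(K: RelationshipMatrix, path: str | Path) -> None:
    """Write a GRM as a full square TSV with entry ids on both margins."""
    pd.DataFrame(K.values, index=list(K.entry_ids), columns=list(K.entry_ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_grm_tsv(path: str | Path, method: str = "custom") -> RelationshipMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(e) for e in df.index)
    if ids != tuple(str(c) for c in df.columns):
        raise ParseError(f"{path}: GRM row and column entry ids differ")
    return RelationshipMatrix(df.to_numpy(dtype=float), ids, method=method)


def write_grm_gcta(K: RelationshipMatrix, prefix: str | Path) -> None:
    """GCTA-style text GRM: <prefix>.grm.gz (i j value, lower triangle,
    1-based) and <prefix>.grm.id."""
    prefix = Path(prefix)
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for i in range(K.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{K.values[i, j]:.10g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for e in K.entry_ids:
            fh.write(f"{e}\t{e}\n")


def read_designs(path: str | Path) -> list[SimulationDesign]:
    """Read a YAML or JSON list of simulation designs."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if isinstance(data, dict):
        data = [data]
    if not isinstance(data, list):
        raise ParseError(f"{path}: expected a list of design records")
    designs = []
    for i, rec in enumerate(data):
        try:
            designs.append(
                SimulationDesign(
                    n=int(rec["n"]),
                    m=int(rec["m"]),
                    H=float(rec["H"]),
                    h2=float(rec["h2"]),
                    reps=int(rec.get("reps", 1)),
                    base_seed=int(rec.get("base_seed", 0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad design record {i}: {exc}") from exc
    return designs


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
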