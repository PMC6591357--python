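"""Transcriptome scores: TDS, ERK score, and BRS.

TDS (thyroid differentiation score) and the ERK score are centered-set
scores: each signature gene's log2 expression is median-centered across the
cohort and the per-sample score is the mean of the centered values over the
signature (16 thyroid function/metabolism genes for TDS, 52 MAPK-pathway
output genes for ERK).  Lower TDS means less differentiated; higher ERK means
more MAPK output.

BRS (BRAF^V600E-RAS score) contrasts single-sample gene-set enrichment
(ssGSEA) of the RAS-like and BRAF-like halves of a 71-gene signature;
negative values are BRAF-like, positive RAS-like (the TCGA sign convention).

The ssGSEA statistic implemented here is the integrated difference between a
weighted in-set ECDF and the uniform out-of-set ECDF over the sample's
descending expression ranking, with rank weights |r|^alpha (alpha = 0.25 by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSignature",
    "centered_set_score",
    "ssgsea",
    "brs",
    "load_signature",
    "write_signature",
    "registry",
    "score_table",
]


@dataclass(frozen=True)
class GeneSignature:
    """An ordered gene set, optionally with BRAF-like/RAS-like class labels."""

    name: str
    genes: tuple[str, ...]
    class_labels: Optional[Mapping[str, str]] = None
    weight_exponent: float = 0.25

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be non-negative")
        if self.class_labels is not None:
            bad = set(self.class_labels.values()) - {"BRAF-like", "RAS-like"}
            if bad:
                raise ValueError(f"unknown class labels {sorted(bad)}")
            object.__setattr__(self, "class_labels", dict(self.class_labels))
        object.__setattr__(self, "genes", tuple(self.genes))

    def subset(self, label: str) -> tuple[str, ...]:
        if self.class_labels is None:
            raise ValueError(f"signature {self.name!r} carries no class labels")
        return tuple(g for g in self.genes if self.class_labels.get(g) == label)


def _present_genes(matrix: pd.DataFrame, signature: GeneSignature) -> list[str]:
    present = [g for g in signature.genes if g in matrix.index]
    missing = [g for g in signature.genes if g not in matrix.index]
    if missing:
        warnings.warn(
            f"{signature.name}: {len(missing)} signature genes absent from the "
            f"matrix (e.g. {missing[:3]}) -- skipped"
        )
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is in the matrix")
    return present


def centered_set_score(matrix: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """Mean of median-centered log2 expression over the signature genes.

    The median is taken per gene across all samples of the supplied matrix
    (callers wanting a different centering cohort pass a different matrix).
    """
    present = _present_genes(matrix, signature)
    sub = matrix.loc[present]
    centered = sub.sub(sub.median(axis=1), axis=0)
    return centered.mean(axis=0).rename(signature.name)


def _ssgsea_sample(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """One-sample ssGSEA: integrated weighted-ECDF difference.

    ``values`` are the sample's expression values; ``in_set`` marks signature
    genes.  Genes are ordered by descending expression (stable, ties broken by
    input order); the rank statistic of the gene at position i (0-based) is
    N - i, weighted as (N - i)^alpha.
    """
    n = values.shape[0]
    order = np.argsort(-values, kind="stable")
    in_ordered = in_set[order]
    n_in = int(in_ordered.sum())
    n_out = n - n_in
    if n_in == 0 or n_out == 0:
        raise ValueError("gene set is empty or covers the whole matrix")
    rank_stat = np.arange(n, 0, -1, dtype=float)  # N..1 along the ordering
    w = rank_stat**alpha
    w_in = np.where(in_ordered, w, 0.0)
    ecdf_in = np.cumsum(w_in) / w_in.sum()
    ecdf_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea(
    matrix: pd.DataFrame,
    gene_set: Iterable[str],
    weight_exponent: float = 0.25,
) -> pd.Series:
    """Per-sample single-sample enrichment score of ``gene_set``.

    Raises when no set gene is present or when a sample's expression is
    all-constant (ranks undefined).
    """
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in matrix.index]
    if not present:
        raise ValueError("gene set has no overlap with the matrix genes")
    in_set = matrix.index.isin(present)
    out = {}
    for sample in matrix.columns:
        values = matrix[sample].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            raise ValueError(f"sample {sample!r} has all-constant expression")
        out[sample] = _ssgsea_sample(values, in_set, weight_exponent)
    return pd.Series(out, name="ssgsea")


def brs(matrix: pd.DataFrame, brs_signature: GeneSignature) -> pd.Series:
    """BRAF^V600E-RAS score: ssGSEA(RAS-like set) - ssGSEA(BRAF-like set),
    scaled by the cohort's maximum absolute contrast so values lie in [-1, 1]
    with the sign preserved (negative = BRAF-like)."""
    ras = brs_signature.subset("RAS-like")
    braf = brs_signature.subset("BRAF-like")
    alpha = brs_signature.weight_exponent
    raw = ssgsea(matrix, ras, alpha) - ssgsea(matrix, braf, alpha)
    scale = raw.abs().max()
    scaled = raw / scale if scale > 0 else raw
    return scaled.rename("brs")


# ---------------------------------------------------------------------------
# Signature files and the shipped registry
# ---------------------------------------------------------------------------

def load_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a signature TSV with columns ``gene`` and optional ``class``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "gene" not in df.columns:
        raise ValueError(f"{path}: signature file needs a 'gene' column")
    labels = None
    if "class" in df.columns and df["class"].notna().any():
        labels = dict(zip(df["gene"], df["class"]))
    return GeneSignature(
        name or Path(path).stem, tuple(df["gene"]), class_labels=labels
    )


def write_signature(signature: GeneSignature, path: str | Path) -> None:
    rows = {"gene": list(signature.genes)}
    if signature.class_labels is not None:
        rows["class"] = [signature.class_labels.get(g, "") for g in signature.genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def registry() -> dict[str, GeneSignature]:
    """The shipped TDS (16 genes), ERK (52) and BRS (71, labelled) signatures.

    Gene identities are curated, editable stand-ins (see the data files'
    headers); sizes and format are the contract, and every scoring operation
    accepts any user-supplied signature file.
    """
    out = {}
    pkg = resources.files("thyromics").joinpath("data")
    for key, fname in (
        ("TDS", "tds16.synthetic.tsv"),
        ("ERK", "erk52.synthetic.tsv"),
        ("BRS", "brs71.synthetic.tsv"),
    ):
        with resources.as_file(pkg.joinpath(fname)) as path:
            out[key] = load_signature(path, name=key)
    return out


def score_table(
    matrix: pd.DataFrame, signatures: Mapping[str, GeneSignature] | None = None
) -> pd.DataFrame:
    """Per-sample TDS, ERK score and BRS as one frame."""
    sigs = signatures or registry()
    return pd.DataFrame(
        {
            "tds": centered_set_score(matrix, sigs["TDS"]),
            "erk": centered_set_score(matrix, sigs["ERK"]),
            "brs": brs(matrix, sigs["BRS"]),
        }
    )
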