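"""96-motif mutation catalogs and reference-signature assignment.

Single-base substitutions are represented on the pyrimidine strand: six
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) in each of 16 flanking
trinucleotide contexts give the standard 96-motif catalog.  Each sample's
catalog (normalized to probabilities) is clustered jointly with a panel of
reference signatures by average-linkage hierarchical clustering on cosine
distance, and the sample is assigned the reference signature its cluster
first co-merges with in the dendrogram.  The nearest-reference cosine
similarity is reported alongside as a sanity check on the assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import VariantRecord

__all__ = [
    "SUBSTITUTIONS",
    "MOTIFS_96",
    "MutationCatalog",
    "SignatureReference",
    "motif_index",
    "build_catalog",
    "assign_signatures",
    "cosine_similarity",
    "synthetic_reference_signatures",
    "load_signature_reference",
    "write_signature_reference",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical motif order: substitution-major, then 5' flank, then 3' flank.
MOTIFS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_MOTIF_INDEX = {m: i for i, m in enumerate(MOTIFS_96)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_index(ref: str, alt: str, five: str, three: str) -> int:
    """Index of the pyrimidine-strand motif for a substitution with flanks.

    Purine reference bases are reverse-complemented (ref, alt and flanks)
    before lookup.
    """
    if ref in "AG":
        ref, alt = _revcomp(ref), _revcomp(alt)
        five, three = _revcomp(three), _revcomp(five)
    return _MOTIF_INDEX[f"{five}[{ref}>{alt}]{three}"]


@dataclass(frozen=True)
class MutationCatalog:
    """Per-sample counts over the 96 motifs."""

    sample: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (96,):
            raise ValueError(f"catalog needs 96 entries, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("negative motif counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError(f"catalog for {self.sample!r} has zero counts")
        return self.counts / self.total


@dataclass(frozen=True)
class SignatureReference:
    """Named reference signatures: each row a probability vector over 96 motifs."""

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 96:
            raise ValueError(f"reference matrix must be n x 96, got {matrix.shape}")
        if len(self.names) != matrix.shape[0]:
            raise ValueError("names/matrix row mismatch")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("reference rows must sum to 1 (+-1e-6)")
        if (matrix < 0).any():
            raise ValueError("negative signature probabilities")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "matrix", matrix)

    def row(self, name: str) -> np.ndarray:
        try:
            return self.matrix[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown signature {name!r}") from None


def _fetch(reference: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Slice bases [start, end) from a dict of sequences or a pyfaidx Fasta."""
    seq = reference[chrom]
    piece = seq[start:end]
    return str(piece).upper()


def build_catalog(
    snvs: Sequence[VariantRecord],
    reference: Mapping[str, str],
    sample: str | None = None,
) -> MutationCatalog:
    """Accumulate SNVs into a 96-motif catalog.

    ``reference`` maps chrom -> sequence (a plain dict or a ``pyfaidx.Fasta``).
    Indels are skipped with a warning; SNVs whose flank would run past a
    contig edge, or whose stated ref disagrees with the reference base, are
    skipped likewise.  Catalog total equals the number of accepted SNVs.
    """
    counts = np.zeros(96, dtype=np.int64)
    name = sample
    for r in snvs:
        if name is None:
            name = r.sample or "sample"
        if not r.is_snv:
            warnings.warn(f"skipping non-SNV {r.chrom}:{r.pos} {r.ref}>{r.alt}")
            continue
        p = r.pos - 1  # 0-based
        if p < 1:
            warnings.warn(f"skipping {r.chrom}:{r.pos}: flank beyond contig start")
            continue
        tri = _fetch(reference, r.chrom, p - 1, p + 2)
        if len(tri) < 3:
            warnings.warn(f"skipping {r.chrom}:{r.pos}: flank beyond contig end")
            continue
        if tri[1] != r.ref.upper():
            warnings.warn(
                f"skipping {r.chrom}:{r.pos}: ref {r.ref} != reference base {tri[1]}"
            )
            continue
        counts[motif_index(r.ref.upper(), r.alt.upper(), tri[0], tri[2])] += 1
    return MutationCatalog(name or "sample", counts)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector in cosine similarity")
    return float(np.dot(a, b) / (na * nb))


def assign_signatures(
    catalogs: Sequence[MutationCatalog],
    reference: SignatureReference,
    linkage_method: str = "average",
    distance: str = "cosine",
) -> pd.DataFrame:
    """Assign each catalog a reference signature by joint hierarchical
    clustering.

    Sample probability vectors and reference rows are clustered together
    (average linkage, cosine distance).  A sample is assigned the reference
    signature contained in the cluster it first co-merges with; when that
    cluster holds several references, the one most cosine-similar to the
    sample wins.  Returns a frame indexed by sample with columns
    ``assigned_signature``, ``cosine_similarity`` (to the assigned reference)
    and ``total_snvs``.
    """
    if not catalogs:
        raise ValueError("no catalogs supplied")
    probs = np.vstack([c.probabilities for c in catalogs])  # raises on zero counts
    n_samples = len(catalogs)
    data = np.vstack([probs, reference.matrix])
    Z = linkage(pdist(data, metric=distance), method=linkage_method)

    n = data.shape[0]
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    assigned: dict[int, int] = {}  # sample leaf -> co-merged cluster's ref leaves known at merge
    assigned_refs: dict[int, list[int]] = {}
    for step, (left, right, _, _) in enumerate(Z):
        li, ri = int(left), int(right)
        merged = members[li] | members[ri]
        members[n + step] = merged
        for a, b in ((members[li], members[ri]), (members[ri], members[li])):
            refs_b = [x for x in b if x >= n_samples]
            if not refs_b:
                continue
            for leaf in a:
                if leaf < n_samples and leaf not in assigned_refs:
                    assigned_refs[leaf] = refs_b
    rows = []
    for i, cat in enumerate(catalogs):
        refs = assigned_refs.get(i)
        if refs is None:  # degenerate: all references merged away first
            sims = [cosine_similarity(probs[i], row) for row in reference.matrix]
            j = int(np.argmax(sims))
        else:
            sims_local = [
                cosine_similarity(probs[i], reference.matrix[r - n_samples])
                for r in refs
            ]
            j = refs[int(np.argmax(sims_local))] - n_samples
        rows.append(
            {
                "sample": cat.sample,
                "assigned_signature": reference.names[j],
                "cosine_similarity": cosine_similarity(
                    probs[i], reference.matrix[j]
                ),
                "total_snvs": cat.total,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Reference panels
# ---------------------------------------------------------------------------

def synthetic_reference_signatures(n_signatures: int = 30) -> SignatureReference:
    """A deterministic **synthetic** 30-signature reference panel.

    The published 30-signature reference set is distributed by COSMIC and is
    not redistributable here, so this panel is a synthetic stand-in with the
    same shape: "Signature 1" concentrates C>T at NpCpG (spontaneous
    deamination-like), "Signature 2" concentrates C>T/C>G at TpCpA and TpCpT
    (APOBEC-like), "Signature 5" is near-flat, and the remaining rows are
    sparse random profiles that are mutually well separated.  Use
    :func:`load_signature_reference` to supply the real COSMIC matrix.
    """
    if not 1 <= n_signatures <= 64:
        raise ValueError("n_signatures must be in [1, 64]")
    rng = np.random.default_rng(20190624)  # fixed: this is a dataset, not a draw
    matrix = np.zeros((n_signatures, 96))
    for i in range(n_signatures):
        base = rng.dirichlet(np.full(96, 0.08))  # sparse profile
        matrix[i] = 0.9 * base + 0.1 / 96
    names = [f"Signature {i + 1}" for i in range(n_signatures)]

    def motif(sub, five, three):
        return _MOTIF_INDEX[f"{five}[{sub}]{three}"]

    if n_signatures >= 1:  # CpG deamination-like
        row = np.full(96, 0.2 / 96)
        for five in _BASES:
            row[motif("C>T", five, "G")] += 0.8 / 4
        matrix[0] = row
    if n_signatures >= 2:  # APOBEC-like
        row = np.full(96, 0.1 / 96)
        for sub in ("C>T", "C>G"):
            for three in ("A", "T"):
                row[motif(sub, "T", three)] += 0.9 / 4
        matrix[1] = row
    if n_signatures >= 5:  # flat, unknown-etiology-like
        flat = np.full(96, 1.0 / 96)
        tilt = rng.normal(0, 0.1, 96)
        row = flat * (1 + 0.2 * np.tanh(tilt))
        matrix[4] = row / row.sum()
    matrix /= matrix.sum(axis=1, keepdims=True)
    return SignatureReference(tuple(names), matrix)


def load_signature_reference(path: str | Path) -> SignatureReference:
    """Read a reference panel TSV: first column ``motif`` (e.g. ``A[C>A]A``),
    one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [m for m in MOTIFS_96 if m not in df.index]
    if missing:
        raise ValueError(f"reference file missing motifs, e.g. {missing[:3]}")
    df = df.loc[list(MOTIFS_96)]
    return SignatureReference(tuple(df.columns), df.to_numpy().T)


def write_signature_reference(reference: SignatureReference, path: str | Path) -> None:
    pd.DataFrame(
        reference.matrix.T, index=pd.Index(MOTIFS_96, name="motif"),
        columns=list(reference.names),
    ).to_csv(path, sep="\t")
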