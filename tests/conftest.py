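"""Shared fixtures: small synthetic objects built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from thyromics.io import VariantRecord
from thyromics.landscape import AlterationMatrix


def make_matrix(histology_counts: dict[str, int]) -> tuple[list[str], dict[str, str]]:
    samples, hist = [], {}
    for h, n in histology_counts.items():
        for i in range(n):
            sid = f"{h.replace(' ', '_').replace('/', '-')}_{i + 1:02d}"
            samples.append(sid)
            hist[sid] = h
    return samples, hist


@pytest.fixture
def oncoprint_fixture() -> AlterationMatrix:
    """Per-sample alteration matrix with the published ATC/wiFTC counts.

    ATC (27): TERT promoter-altered in 15, TP53 in 13, CDKN2A in 6 (two also
    TP53-mutant), PTEN in 3 TSG-only samples, so 20 samples carry any TSG hit.
    wiFTC (12): TERT altered in 11.
    """
    samples, hist = make_matrix({"ATC": 27, "wiFTC": 12})
    genes = ["TERT", "TP53", "CDKN2A", "PTEN", "BRAF"]
    roles = {"TERT": "telomere", "TP53": "TSG", "CDKN2A": "TSG",
             "PTEN": "TSG", "BRAF": "oncogene"}
    mat = AlterationMatrix(samples, hist, genes, roles)
    atc = [s for s in samples if hist[s] == "ATC"]
    wiftc = [s for s in samples if hist[s] == "wiFTC"]
    for s in atc[:15]:
        mat.add(s, "TERT", "promoter")
    for s in atc[:13]:
        mat.add(s, "TP53", "LoF")
    for s in atc[11:17]:  # 2 overlap TP53, 4 new -> TSG union 17
        mat.add(s, "CDKN2A", "CN_loss")
    for s in atc[17:20]:  # 3 more -> TSG union 20
        mat.add(s, "PTEN", "LoF")
    for s in wiftc[:11]:
        mat.add(s, "TERT", "promoter")
    return mat


def make_variant(**kwargs) -> VariantRecord:
    defaults = dict(
        chrom="1", pos=100, ref="C", alt="T", gene="TP53", effect="missense",
        popmax_af=None, polyphen_call="missing", sift_call="missing",
        somatic_status="unknown", sample="s1", platform="WGS",
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


@pytest.fixture
def toy_expression() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{i}" for i in range(6)]
    return pd.DataFrame(
        rng.normal(5, 1, size=(20, 6)), index=genes, columns=samples
    )
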