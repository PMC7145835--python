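"""Packaged reference data from the Alzheimer's-psychosis case study.

Three small curated tables accompany the package so that overlap counts and
summary-table identities can be checked without any external download:

* ``ad_psychosis_shared_genes.txt`` -- the 90 gene symbols reported shared
  between the Alzheimer's disease (AD) and psychosis interactome seed
  lists.
* ``vitamin_d_overlap_centralities.tsv`` -- the 21 genes shared between
  the AD-psychosis combined network and the Vitamin D perturbation
  network, with their published normalized degree and betweenness
  centralities (ranked by betweenness).
* ``reported_network_summaries.tsv`` -- published per-network node/edge
  counts and mean centralities. ``degree_identity_holds`` marks whether
  the printed mean degree centrality equals 2E/(N(N-1)) truncated to three
  significant figures; one published row (Vitamin D) fails that identity
  under any rounding and is flagged 0.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import GeneSet

__all__ = [
    "load_ad_psychosis_shared_genes",
    "load_vitamin_d_overlap",
    "load_reported_network_summaries",
]


def _path(name: str):
    return resources.files("triplefocus.data").joinpath(name)


def load_ad_psychosis_shared_genes() -> GeneSet:
    """The 90 genes shared by the AD and psychosis seed lists."""
    text = _path("ad_psychosis_shared_genes.txt").read_text()
    symbols = [
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GeneSet("ad_psychosis_shared", frozenset(symbols))


def load_vitamin_d_overlap() -> pd.DataFrame:
    """Published centralities of the AD-psychosis x Vitamin D overlap genes."""
    with resources.as_file(_path("vitamin_d_overlap_centralities.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_reported_network_summaries() -> pd.DataFrame:
    """Published network characteristic rows (see module docstring)."""
    with resources.as_file(_path("reported_network_summaries.tsv")) as p:
        return pd.read_csv(p, sep="\t")
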