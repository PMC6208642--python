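import numpy as np
import pandas as pd
import pytest

from pneumotype import (
    CommunityConfig,
    detection_filter,
    generate_community,
    jsd_distance,
    to_relative,
)
from pneumotype.taxassign import TaxonomyTree


@pytest.fixture(scope="session")
def planted():
    """Default planted 3-component community (n=40, T=30) with its
    detection-filtered table, relative abundance and sqrt-JSD distances."""
    table, labels = generate_community(CommunityConfig(seed=0))
    _, kept = detection_filter(to_relative(table))
    filtered = table.subset_taxa(kept)
    rel = to_relative(filtered)
    dist = jsd_distance(rel)
    return {"table": filtered, "raw": table, "labels": labels,
            "rel": rel, "dist": dist}


@pytest.fixture()
def toy_tree():
    """Small taxonomy: two phyla under one kingdom; genus gA holds two
    species, family fA holds a second genus."""
    parent = {
        "root": "root",
        "k1": "root",
        "pA": "k1", "cA": "pA", "oA": "cA", "fA": "oA",
        "gA": "fA", "s1": "gA", "s2": "gA",
        "gA2": "fA", "s4": "gA2",
        "pB": "k1", "cB": "pB", "oB": "cB", "fB": "oB",
        "gB": "fB", "s3": "gB",
    }
    rank = {
        "root": "root", "k1": "kingdom",
        "pA": "phylum", "cA": "class", "oA": "order", "fA": "family",
        "gA": "genus", "s1": "species", "s2": "species",
        "gA2": "genus", "s4": "species",
        "pB": "phylum", "cB": "class", "oB": "order", "fB": "family",
        "gB": "genus", "s3": "species",
    }
    return TaxonomyTree(parent=parent, rank=rank)


@pytest.fixture()
def hand_rel():
    """Tiny relative-abundance table with known values."""
    from pneumotype import AbundanceTable

    counts = pd.DataFrame(
        {"s1": [10, 30, 60], "s2": [2, 2, 0], "s3": [0, 0, 5]},
        index=["ta", "tb", "tc"],
    )
    return to_relative(AbundanceTable(counts))
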