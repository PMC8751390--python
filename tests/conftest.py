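import numpy as np
import pandas as pd
import pytest

from rhizodmm import CountTable, SampleMetadata, TaxonomyTable


@pytest.fixture
def small_counts() -> CountTable:
    data = pd.DataFrame(
        [[6, 0, 2, 4], [2, 2, 2, 4], [10, 0, 0, 5]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return CountTable(data)


@pytest.fixture
def small_taxonomy() -> TaxonomyTable:
    data = pd.DataFrame(
        {
            "kingdom": ["Bacteria", "Bacteria", "Eukaryota", "NA", "Bacteria"],
            "phylum": ["Proteobacteria", "Cyanobacteria", "Streptophyta", "NA", "Bacteroidetes"],
            "class": ["Gamma", "Chloroplast", "NA", "NA", "NA"],
            "family": ["Pseudomonadaceae", "NA", "NA", "NA", "NA"],
        },
        index=["t1", "t2", "t3", "t4", "t5"],
    )
    return TaxonomyTable(data)


@pytest.fixture
def study_metadata() -> SampleMetadata:
    rows = []
    for g, p in [("Col", "2x"), ("Col", "4x"), ("Ler", "2x"), ("Ler", "4x")]:
        for j in range(2):
            rows.append({"sample_id": f"{g}-{p}-r{j}", "genotype": g, "ploidy": p,
                         "block": f"B{j + 1}", "is_soil_control": False})
    for j in range(2):
        rows.append({"sample_id": f"soil-r{j}", "genotype": None, "ploidy": None,
                     "block": f"B{j + 1}", "is_soil_control": True})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
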