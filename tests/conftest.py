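
import pandas as pd
import pytest

from chemosig.chem import GROUPS, CompoundTable
from chemosig.protocol import make_protocol


@pytest.fixture(scope="session")
def default_protocol():
    return make_protocol()


def make_table(counts_per_group: dict[str, list[int]], n_per_group: int = 10,
               value: float = 10.0) -> CompoundTable:
    """Build a CompoundTable where compound i is detected in exactly
    counts_per_group[g][i] samples of group g (deterministic placement)."""
    n_compounds = len(next(iter(counts_per_group.values())))
    sample_rows = []
    for g in GROUPS:
        sex, strain = g.split("-", 1)
        for i in range(n_per_group):
            sample_rows.append(
                {"sample_id": f"{g}-{i + 1:02d}", "sex": sex, "strain": strain,
                 "individual": i + 1}
            )
    sample_meta = pd.DataFrame(sample_rows).set_index("sample_id")
    comp_ids = [f"c{i}" for i in range(n_compounds)]
    ab = pd.DataFrame(0.0, index=comp_ids, columns=sample_meta.index)
    for g, counts in counts_per_group.items():
        cols = [s for s in sample_meta.index if s.startswith(f"{g}-")]
        for i, k in enumerate(counts):
            ab.loc[comp_ids[i], cols[:k]] = value
    meta = pd.DataFrame(
        {"class": ["VOC"] * n_compounds, "family": [None] * n_compounds},
        index=pd.Index(comp_ids, name="compound_id"),
    )
    return CompoundTable(abundance=ab, compound_meta=meta, sample_meta=sample_meta)
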