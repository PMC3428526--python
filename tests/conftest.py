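import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lfqpipe import PeptideQuantTable, ProteinQuantTable, StudyDesign

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_design(n1=5, n2=4, labels=("ER+", "ER-"), n_wtl=0, n_lcm=0) -> StudyDesign:
    rows = []
    for i in range(n_wtl):
        rows.append((f"WTL{i + 1:02d}", "WTL-CTRL", ""))
    for i in range(n_lcm):
        rows.append((f"LCM{i + 1:02d}", "LCM-CTRL", ""))
    for i in range(n1):
        rows.append((f"S{i + 1:02d}", "EXPERIMENTAL", labels[0]))
    for i in range(n2):
        rows.append((f"S{n1 + i + 1:02d}", "EXPERIMENTAL", labels[1]))
    frame = pd.DataFrame(
        {
            "sample_class": [r[1] for r in rows],
            "group_label": [r[2] for r in rows],
            "order_index": np.arange(len(rows)),
        },
        index=pd.Index([r[0] for r in rows], name="sample_id"),
    )
    return StudyDesign(frame)


def make_peptides(intensity: pd.DataFrame, parents=None, reverse=None,
                  msms=None) -> PeptideQuantTable:
    """Wrap an intensity frame into a peptide table with simple defaults."""
    idx = intensity.index
    if parents is None:
        parents = pd.Series([("P1",)] * len(idx), index=idx)
    else:
        parents = pd.Series(
            [g if isinstance(g, tuple) else (g,) for g in parents], index=idx
        )
    if reverse is None:
        reverse = pd.Series(False, index=idx)
    else:
        reverse = pd.Series(list(reverse), index=idx).astype(bool)
    if msms is None:
        msms = intensity.notna().astype(int)
    return PeptideQuantTable(
        intensity=intensity.astype(float),
        msms=msms,
        protein_groups=parents.rename("protein_groups"),
        is_reverse=reverse.rename("is_reverse"),
    )


def make_proteins(abundance: pd.DataFrame, msms=None, reverse=None) -> ProteinQuantTable:
    idx = abundance.index
    if msms is None:
        msms = abundance.notna().astype(int)
    if reverse is None:
        reverse = pd.Series(False, index=idx)
    else:
        reverse = pd.Series(list(reverse), index=idx).astype(bool)
    return ProteinQuantTable(
        abundance=abundance.astype(float),
        msms=msms,
        entry_names=pd.Series([(str(i),) for i in idx], index=idx, name="entry_names"),
        is_reverse=reverse.rename("is_reverse"),
    )


@pytest.fixture
def design_5v4() -> StudyDesign:
    return make_design()


@pytest.fixture
def exp_samples(design_5v4) -> list[str]:
    return design_5v4.experimental
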