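import numpy as np
import pytest

from titinmech import polymer_models as pm
from titinmech.domain_kinetics import RateSet


@pytest.fixture
def params():
    return pm.PolymerParams()


@pytest.fixture
def geom():
    return pm.DomainGeometry()


@pytest.fixture
def topo():
    return pm.DisulfideTopology()


@pytest.fixture
def conservative_topo():
    # loop_BG = loop_BF + loop_FG: released residues exactly conserved
    # along every path, which is what the additivity identities need
    return pm.DisulfideTopology(loop_BF=51, loop_FG=11, loop_BG=62)


@pytest.fixture
def rates():
    return RateSet()


def build_parent_fasta(tmp_path, domain_seqs, linker="GSGSGSGSGS", leader="MTTQAP"):
    """Write a synthetic parent FASTA containing the given domains and
    return (fasta_path, annotation DataFrame with 1-based coordinates)."""
    import pandas as pd

    parts = [leader]
    rows = []
    pos = len(leader)
    for i, seq in enumerate(domain_seqs):
        start = pos + 1
        parts.append(seq)
        pos += len(seq)
        rows.append({"id": f"dom{i:02d}", "start": start, "end": pos,
                     "region": "I-band"})
        parts.append(linker)
        pos += len(linker)
    fasta = tmp_path / "parent.fasta"
    fasta.write_text(">synthetic_parent\n" + "".join(parts) + "\n")
    return fasta, pd.DataFrame(rows)
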