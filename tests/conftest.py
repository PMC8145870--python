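import numpy as np
import pytest

from jointscreen.cloning import CloningDesign, GeneInsert, build_recombinant
from jointscreen.enzymes import NCOI, NOTI
from jointscreen.simulate import design_from_config, make_sim_config

# Toy ligation worked out by hand: vector opened at NcoI (pos 3, cut after
# C) and NotI (pos 12, cut after GC); insert trimmed at its own sites; the
# rejoined circle reads AAAC|CATGG-cat-GC|GGCCGC-AAA.
TOY_VECTOR = "AAACCATGGTTTGCGGCCGCAAA"
TOY_INSERT = "ggCCATGGcatGCGGCCGCtt"
TOY_RECOMBINANT = "AAACCATGGCATGCGGCCGCAAA"


@pytest.fixture
def toy_design():
    return CloningDesign(
        vector_seq=TOY_VECTOR,
        enzyme_5p=NCOI,
        enzyme_3p=NOTI,
        inserts=[GeneInsert(gene_id="toy", fragment_seq=TOY_INSERT)],
    )


@pytest.fixture
def toy_recombinant(toy_design):
    return build_recombinant(toy_design, toy_design.inserts[0])


@pytest.fixture(scope="session")
def small_config():
    """Three synthetic genes, deterministic fragments."""
    return make_sim_config(n_genes=3, seed=11, coding_len_range=(200, 400))


@pytest.fixture(scope="session")
def small_design(small_config):
    rng = np.random.default_rng(np.random.SeedSequence([11, 0xD0]))
    return design_from_config(small_config, rng)
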