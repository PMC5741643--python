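from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cyclomine.mining import PrecursorCandidate, OrfCandidate, scan_cd_motif
from cyclomine.synthetic import build_template_library, build_transcriptome, default_bundle

KB1 = "GLPVCGETCVGGTCNTPGCTCSWPVCTRN"
CYO2 = "GIPCGESCVWIPCISSAIGCSCKSKVCYRN"


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def templates():
    return build_template_library()


@pytest.fixture(scope="session")
def template_map(templates):
    return {t.name: t for t in templates}


@pytest.fixture(scope="session")
def small_sim():
    """One instance of every species plus decoys, fixed seed."""
    records, fpkm, truth = build_transcriptome(
        n_per_species=1, n_decoys=20, rng_seed=11
    )
    return records, fpkm, truth


def candidate_from_protein(protein: str, flags: tuple[str, ...] = ()) -> PrecursorCandidate:
    """Wrap a bare protein as a mined candidate for anchoring tests."""
    orf = OrfCandidate(
        transcript_id="fixture", frame=1, nt_span=(0, 3 * len(protein)), protein=protein
    )
    hits = tuple(scan_cd_motif(protein))
    if not hits:
        flags = tuple(dict.fromkeys(flags + ("abnormal_cysteines",)))
    return PrecursorCandidate(
        orf=orf, motif_hits=hits, similarity=0.0, best_ref="", flags=flags,
        provenance=("fixture",),
    )
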