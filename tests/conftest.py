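"""Shared fixtures: a small toy genome and one study-scale simulation
(genome, WT / TF-deleted / naked libraries, tracks) reused across the
detection, asymmetry and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fungatac.insertions import track_from_fragments
from fungatac.synthetic import (FootprintSpec, SimulationConfig, make_genome,
                                simulate_condition)

STUDY_SEED = 20260928

#: the study conditions: compact 0.5 Mb genome, 400 promoters, 300 of
#: them carrying a bound TF motif (occupancy 0.9, kappa 2) and 100 an
#: unbound decoy instance of the same consensus; 1e5 fragments.
STUDY_MOTIFS = [("prtT", "CCGHCGG", 300), ("decoy", "CCGHCGG", 100)]
STUDY_SPEC = (FootprintSpec("prtT", "CCGHCGG", 300, occupancy=0.9, kappa=2.0),)


def study_genome(seed=STUDY_SEED):
    return make_genome(2, [250_000, 250_000], 400, seed=seed,
                       gene_length_range=(400, 900), motifs=STUDY_MOTIFS)


def study_config(seed=STUDY_SEED, n_fragments=100_000):
    return SimulationConfig(n_fragments=n_fragments, footprint_spec=STUDY_SPEC,
                            seed=seed)


@pytest.fixture(scope="session")
def genome():
    return study_genome()


@pytest.fixture(scope="session")
def sim_wt(genome):
    return simulate_condition(genome, study_config(), "WT")


@pytest.fixture(scope="session")
def sim_naked(genome):
    return simulate_condition(genome, study_config(), "naked")


@pytest.fixture(scope="session")
def sim_deleted(genome):
    return simulate_condition(genome, study_config(), "TF-deleted:prtT")


@pytest.fixture(scope="session")
def track_wt(genome, sim_wt):
    return track_from_fragments(sim_wt[0], genome.chrom_lengths)


@pytest.fixture(scope="session")
def track_naked(genome, sim_naked):
    return track_from_fragments(sim_naked[0], genome.chrom_lengths)


@pytest.fixture(scope="session")
def track_deleted(genome, sim_deleted):
    return track_from_fragments(sim_deleted[0], genome.chrom_lengths)


@pytest.fixture(scope="session")
def wt_peaks(track_wt):
    from fungatac.peaks import call_peaks

    return call_peaks(track_wt)


@pytest.fixture(scope="session")
def motif_instances(genome):
    """Planted prtT motif coordinates (the scan anchor for profiles)."""
    return pd.DataFrame(
        [{"chrom": m.chrom, "start": m.start, "end": m.end, "strand": m.strand}
         for m in genome.planted_motifs if m.motif_id == "prtT"])


@pytest.fixture(scope="session")
def toy_genome():
    return make_genome(1, [60_000], 25, seed=7, gene_length_range=(400, 900),
                       motifs=[("prtT", "CCGHCGG", 25)])
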