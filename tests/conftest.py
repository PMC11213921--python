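import numpy as np
import pandas as pd
import pytest

from locustal.motifs import transition_probabilities
from locustal.synthetic import generate_triplet_population


def responsive_assignment(rng, n_cells, n_stim=3):
    """Random motif assignment guaranteeing each cell at least one
    excitatory motif (ids 3-6) across the stimuli."""
    a = rng.choice(range(1, 7), size=(n_cells, n_stim))
    for row in a:
        if not np.any(row >= 3):
            row[rng.integers(n_stim)] = rng.integers(3, 7)
    return a


def tmaps_from_population(pop, k=6):
    """Per-animal transition maps from a generate_triplet_population output."""
    frames = []
    for aid, phen, trips in pop:
        df = pd.DataFrame(trips, columns=["Lct", "Laa", "LaaLct"])
        df["animal"] = aid
        df["phenotype"] = phen
        frames.append(df)
    trip = pd.concat(frames, ignore_index=True)
    tmaps = transition_probabilities(trip, k=k)
    phen = {aid: p for aid, p, _ in pop}
    for t in tmaps:
        t.phenotype = phen[t.animal]
    return tmaps


# base triplet repertoire shared by both phenotypes; the planted phenotypes
# differ in synergy-enriched vs antagonism-enriched triplets
BASE_TRIPLETS = {(2, 5, 5): 0.2, (3, 6, 3): 0.15, (2, 4, 4): 0.2,
                 (1, 3, 3): 0.15, (4, 4, 5): 0.15, (6, 6, 6): 0.15}
SYNERGY_TRIPLETS = {**BASE_TRIPLETS, (1, 1, 4): 0.25, (1, 1, 6): 0.15}
ANTAGONISM_TRIPLETS = {**BASE_TRIPLETS, (6, 6, 3): 0.25, (2, 2, 1): 0.15}


@pytest.fixture
def planted_phenotype_tmaps():
    pop = (generate_triplet_population(SYNERGY_TRIPLETS, 15, 60, seed=7,
                                       phenotype="greg")
           + generate_triplet_population(ANTAGONISM_TRIPLETS, 15, 60, seed=8,
                                         phenotype="soli"))
    return tmaps_from_population(pop)
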