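import numpy as np
import pytest

from cjsage.data import EncounterHistory, Population, StudyDataset, BreedingRecord


@pytest.fixture
def two_pop_dataset():
    """Small hand-built study: two populations with different windows."""
    pops = {
        "north": Population("north", 2000, 2005),
        "south": Population("south", 2002, 2006),
    }
    hists = [
        EncounterHistory("n1", "north", "female", 1, 1, (1, 1, 0, 1, 0, 0)),
        EncounterHistory("n2", "north", "male", 3, 2, (1, 0, 1, 1)),
        EncounterHistory("n3", "north", "female", 3, None, (1, 1, 1, 1)),
        EncounterHistory("n4", "north", "male", 5, None, (1, 0)),
        EncounterHistory("s1", "south", "male", 1, 1, (1, 0, 0, 1, 1)),
        EncounterHistory("s2", "south", "female", 2, None, (1, 1, 0, 0)),
        EncounterHistory("s3", "south", "female", 4, 1, (1, 1)),
    ]
    breeding = [
        BreedingRecord("n1", "north", 1, 1),
        BreedingRecord("n1", "north", 2, 0),
        BreedingRecord("n3", "north", 4, 1),
        BreedingRecord("s1", "south", 4, 1),
        BreedingRecord("s2", "south", 2, 0),
    ]
    return StudyDataset(populations=pops, histories=hists, breeding=breeding)


def brute_force_cjs_loglik(detections, phi, p):
    """Independent oracle: enumerate every latent alive/dead sequence.

    The bird is alive at entry; each latent sequence fixes the death interval
    (or survival to the end) and its probability times the detection
    probability of the observed pattern is accumulated.
    """
    y = list(detections)
    L = len(y)
    assert y[0] == 1
    total = 0.0
    # death after interval k (bird alive at occasions entry..entry+k), k=0..L-1;
    # k = L-1 means alive through the final occasion
    for k in range(L):
        prob = 1.0
        for t in range(k):
            prob *= phi[t]
        if k < L - 1:
            prob *= 1.0 - phi[k]
        ok = True
        for t in range(1, L):
            if t <= k:
                prob *= p[t - 1] if y[t] else 1.0 - p[t - 1]
            elif y[t]:
                ok = False
                break
        if ok:
            total += prob
    return np.log(total) if total > 0 else -np.inf
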