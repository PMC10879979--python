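import numpy as np
import pytest

from persnet.records import AlterRecord, EgoNetwork


def make_network(
    n,
    edges=(),
    pid="p1",
    timepoint="pandemic",
    relationships=None,
    **attr_lists,
):
    """Build an ego network with ``n`` alters and the given alter-alter edges.

    ``attr_lists`` maps AlterRecord field names to per-alter value lists,
    e.g. ``age=[30, 40, 50]``.
    """
    alters = []
    for i in range(n):
        kwargs = {k: v[i] for k, v in attr_lists.items()}
        rel = relationships[i] if relationships else "friend"
        alters.append(AlterRecord(alter_id=f"a{i + 1}", relationship=rel, **kwargs))
    ties = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        ties[i, j] = ties[j, i] = True
    return EgoNetwork(participant_id=pid, timepoint=timepoint, alters=alters, ties=ties)


def random_network(rng, n=None, pid="p1"):
    """Random tie matrix over 1..8 alters with random attributes."""
    if n is None:
        n = int(rng.integers(1, 9))
    ties = np.zeros((n, n), dtype=bool)
    iu = np.triu_indices(n, 1)
    ties[iu] = rng.random(len(iu[0])) < rng.random()
    ties |= ties.T
    rels = rng.choice(["parent", "friend", "spouse", "coworker"], n)
    alters = [
        AlterRecord(
            alter_id=f"a{i + 1}",
            relationship=str(rels[i]),
            age=float(rng.integers(18, 90)) if rng.random() > 0.1 else None,
            sex=str(rng.choice(["woman", "man"])) if rng.random() > 0.1 else None,
            race=str(rng.choice(["white", "asian", "african_american"])),
            contact_freq=str(rng.choice(["daily", "weekly", "monthly", "less", "unknown"])),
            years_known=float(rng.integers(0, 40)),
            distance_gt_15mi=bool(rng.random() < 0.3),
            drinks=bool(rng.random() < 0.2),
            smokes=bool(rng.random() < 0.1),
            nonexerciser=bool(rng.random() < 0.4),
            bad_diet=bool(rng.random() < 0.25),
            negative_influence=bool(rng.random() < 0.35),
        )
        for i in range(n)
    ]
    return EgoNetwork(participant_id=pid, timepoint="pandemic", alters=alters, ties=ties)


@pytest.fixture
def rng():
    return np.random.default_rng(20240206)
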