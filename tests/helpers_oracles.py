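"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's implementations (and sklearn): plain
loops and breadth-first search, so agreement is a genuine cross-check.
"""

import numpy as np


def brute_force_hbonds(coords, topology, distance_cutoff=3.0, angle_cutoff=135.0,
                       fluorine_acceptors=True):
    """All (donor, hydrogen, acceptor) triples meeting the criteria, by
    direct enumeration: H bonded to nearest N/O/S within 1.2 Å, acceptors
    N/O/S(/F), inter-residue only."""
    donors = []
    for h, ah in enumerate(topology.atoms):
        if ah.element != "H":
            continue
        best, best_d = None, 1.2
        for i, ai in enumerate(topology.atoms):
            if ai.element in ("N", "O", "S"):
                d = np.linalg.norm(coords[h] - coords[i])
                if d <= best_d:
                    best, best_d = i, d
        if best is not None:
            donors.append((best, h))
    acc_elements = ("N", "O", "S", "F") if fluorine_acceptors else ("N", "O", "S")
    triples = set()
    for d_i, h_i in donors:
        for a_i, aa in enumerate(topology.atoms):
            if aa.element not in acc_elements or a_i == d_i:
                continue
            if aa.residue_index == topology.atoms[d_i].residue_index:
                continue
            if np.linalg.norm(coords[a_i] - coords[d_i]) > distance_cutoff:
                continue
            v1 = coords[d_i] - coords[h_i]
            v2 = coords[a_i] - coords[h_i]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_cutoff:
                triples.add((d_i, h_i, a_i))
    return triples


def brute_force_dbscan(points, eps, min_samples):
    """Textbook DBSCAN by breadth-first search over the eps-neighborhood
    graph; labels with -1 for noise, cluster ids in discovery order."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbors = [np.nonzero(dist[i] <= eps)[0] for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    queue.append(k)
        cluster += 1
    return labels


def labels_equivalent(a, b):
    """True if two labelings agree up to a permutation of cluster ids
    (noise label -1 must match exactly)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or np.any((a == -1) != (b == -1)):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    seen = list(mapping.values())
    return len(seen) == len(set(seen))
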