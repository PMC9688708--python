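"""Naive reference implementations of the validity indices.

Straight double-loop transcriptions of the textbook definitions, kept
deliberately independent of the package (no shared helpers) so they can
serve as oracles in equivalence tests.
"""

import math

import numpy as np


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def silhouette_samples_naive(points, labels):
    points = [list(map(float, p)) for p in np.atleast_2d(points)]
    labels = list(labels)
    clusters = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(i)
    out = []
    for i, p in enumerate(points):
        own = clusters[labels[i]]
        if len(own) == 1:
            out.append(0.0)
            continue
        a = sum(_dist(p, points[j]) for j in own if j != i) / (len(own) - 1)
        b = min(
            sum(_dist(p, points[j]) for j in members) / len(members)
            for lab, members in clusters.items() if lab != labels[i]
        )
        denom = max(a, b)
        out.append(0.0 if denom == 0 else (b - a) / denom)
    return np.array(out)


def silhouette_mean_naive(points, labels):
    return float(np.mean(silhouette_samples_naive(points, labels)))


def calinski_harabasz_naive(points, labels):
    points = [list(map(float, p)) for p in np.atleast_2d(points)]
    labels = list(labels)
    n, d = len(points), len(points[0])
    grand = [sum(p[c] for p in points) / n for c in range(d)]
    clusters = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(points[i])
    k = len(clusters)
    B = W = 0.0
    for members in clusters.values():
        centroid = [sum(p[c] for p in members) / len(members) for c in range(d)]
        B += len(members) * sum((centroid[c] - grand[c]) ** 2 for c in range(d))
        for p in members:
            W += sum((p[c] - centroid[c]) ** 2 for c in range(d))
    if W == 0:
        return math.inf
    return (B / (k - 1)) / (W / (n - k))


def davies_bouldin_naive(points, labels):
    points = [list(map(float, p)) for p in np.atleast_2d(points)]
    labels = list(labels)
    d = len(points[0])
    clusters = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(points[i])
    labs = list(clusters)
    centroids = {
        lab: [sum(p[c] for p in members) / len(members) for c in range(d)]
        for lab, members in clusters.items()
    }
    spreads = {
        lab: sum(_dist(p, centroids[lab]) for p in members) / len(members)
        for lab, members in clusters.items()
    }
    total = 0.0
    for li in labs:
        worst = 0.0
        for lj in labs:
            if lj == li:
                continue
            m = _dist(centroids[li], centroids[lj])
            worst = max(worst, (spreads[li] + spreads[lj]) / m)
        total += worst
    return total / len(labs)
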