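"""Independent brute-force implementations used only to check the package.

Everything here is written directly from the mathematical definitions with
plain Python loops and shares no code with the implementation under test.
"""

import math

import numpy as np


def loss_brute_force(S):
    """Symmetric contrastive loss, transcribed term by term.

    Per anchor i:  -1/2 ln[exp(s_ii)/(exp(s_ii)+sum_{j!=i} exp(s_ij))]
                   -1/2 ln[exp(s_ii)/(exp(s_ii)+sum_{j!=i} exp(s_ji))]
    summed over anchors.
    """
    S = np.asarray(S, dtype=float)
    M = S.shape[0]
    total = 0.0
    for i in range(M):
        row_den = math.exp(S[i, i]) + sum(
            math.exp(S[i, j]) for j in range(M) if j != i)
        col_den = math.exp(S[i, i]) + sum(
            math.exp(S[j, i]) for j in range(M) if j != i)
        total += -0.5 * math.log(math.exp(S[i, i]) / row_den)
        total += -0.5 * math.log(math.exp(S[i, i]) / col_den)
    return total


def euclidean(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def knn_sets(Q, R, k):
    """k nearest reference indices per query row; ties by index order."""
    out = []
    for i in range(len(Q)):
        dists = [(euclidean(Q[i], R[j]), j) for j in range(len(R))]
        dists.sort(key=lambda t: (t[0], t[1]))
        out.append([j for _, j in dists[:k]])
    return out


def recall_at_k_brute(Q, R, k):
    hits = sum(1 for i, nn in enumerate(knn_sets(Q, R, k)) if i in nn)
    return hits / len(Q)


def cell_type_at_k_brute(Q, R, ql, rl, k):
    total = 0.0
    for i, nn in enumerate(knn_sets(Q, R, k)):
        total += sum(1 for j in nn if rl[j] == ql[i]) / k
    return total / len(Q)


def median_rank_brute(Q, R):
    """Rank of the matched reference; matched pair wins ties."""
    ranks = []
    for i in range(len(Q)):
        d_match = euclidean(Q[i], R[i])
        rank = 1 + sum(1 for j in range(len(R))
                       if euclidean(Q[i], R[j]) < d_match)
        ranks.append(rank)
    ranks.sort()
    n = len(ranks)
    if n % 2 == 1:
        med = float(ranks[n // 2])
    else:
        med = (ranks[n // 2 - 1] + ranks[n // 2]) / 2.0
    return med, med / len(R)


def silhouette_brute(X, labels):
    """Mean silhouette width from the definition; singletons get 0."""
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = len(labels)
    clusters = {}
    for i, t in enumerate(labels):
        clusters.setdefault(t, []).append(i)
    widths = []
    for i in range(n):
        own = clusters[labels[i]]
        if len(own) == 1:
            widths.append(0.0)
            continue
        a = sum(euclidean(X[i], X[j]) for j in own if j != i) / (len(own) - 1)
        b = min(
            sum(euclidean(X[i], X[j]) for j in members) / len(members)
            for t, members in clusters.items() if t != labels[i])
        widths.append((b - a) / max(a, b))
    return sum(widths) / n


def pca_axes_eig(X, n_components):
    """Principal axes via covariance eigendecomposition (population, n-1)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return vecs[:, order[:n_components]].T, vals[order[:n_components]]
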