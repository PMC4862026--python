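"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — exhaustive enumeration and
direct formula evaluation — and shares no code with the package.
"""

from itertools import combinations

import numpy as np
from scipy import stats

MIN_GAIN = 1e-12


def pair_count_auc(scores, labels):
    """AUC as the Mann-Whitney pair statistic: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def welch_formula(a, b):
    """Welch t, Welch-Satterthwaite df and two-sided p, written out."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def exact_mannwhitney_p(a, b):
    """Two-sided exact permutation p for the Mann-Whitney U statistic.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes; two-sided via the symmetric statistic |U - mn/2|.
    """
    a = list(a)
    b = list(b)
    pooled = a + b
    n1 = len(a)
    center = n1 * len(b) / 2.0

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    observed = abs(u_stat(a, b) - center)
    idx = range(len(pooled))
    hits = total = 0
    for comb in combinations(idx, n1):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in idx if i not in comb]
        total += 1
        if abs(u_stat(sa, sb) - center) >= observed - 1e-12:
            hits += 1
    return hits / total


class BruteTree:
    """Exhaustive-search Gini decision tree for small complete datasets.

    Considers every feature and every midpoint between consecutive
    distinct values; ties resolve to the lowest feature index, then the
    lowest threshold; leaves with tied votes predict class 0.
    """

    def __init__(self, X, y):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        assert not np.isnan(self.X).any(), "oracle handles complete data only"
        self.root = self._grow(np.arange(len(y)))

    def _gini(self, npos, m):
        fp = npos / m
        return 1.0 - fp * fp - (1.0 - fp) * (1.0 - fp)

    def _grow(self, idx):
        y = self.y[idx]
        m = len(idx)
        npos = int(y.sum())
        majority = 1 if 2 * npos > m else 0
        if npos == 0 or npos == m:
            return ("leaf", majority)
        parent = self._gini(npos, m)
        best = (MIN_GAIN, None, None)
        for f in range(self.X.shape[1]):
            v = self.X[idx, f]
            order = np.argsort(v, kind="mergesort")
            sv, sy = v[order], y[order]
            cpos = 0
            for b in range(m - 1):
                cpos += sy[b]
                if sv[b + 1] <= sv[b]:
                    continue
                t = 0.5 * (sv[b] + sv[b + 1])
                if t <= sv[b] or t >= sv[b + 1]:
                    t = sv[b]
                nl, lp = b + 1, cpos
                nr, rp = m - nl, npos - lp
                plf, prf = lp / nl, rp / nr
                child = (
                    nl * (1.0 - plf * plf - (1.0 - plf) * (1.0 - plf))
                    + nr * (1.0 - prf * prf - (1.0 - prf) * (1.0 - prf))
                ) / m
                gain = parent - child
                if gain > best[0]:
                    best = (gain, f, t)
        if best[1] is None:
            return ("leaf", majority)
        _, f, t = best
        left = idx[self.X[idx, f] <= t]
        right = idx[self.X[idx, f] > t]
        if len(left) == 0 or len(right) == 0:
            return ("leaf", majority)
        return ("node", f, t, self._grow(left), self._grow(right))

    def predict_one(self, x):
        node = self.root
        while node[0] == "node":
            _, f, t, l, r = node
            node = l if x[f] <= t else r
        return node[1]

    def predict(self, X):
        return np.array([self.predict_one(x) for x in np.asarray(X, dtype=float)])
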