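"""Synthetic ratio matrices with a planted organelle "shadow".

The generator emulates the statistical structure the classifier exploits
in real comparative proteomics data: a module of organelle proteins that
shifts coordinately — slightly up or down, by a per-experiment amount
shared across the module — against a background of proteins that do not
share that shift.  Cell values are

    x[i, e] = mu_i + delta_e * [i in organelle]
                   + delta_e^(module m) * [i in module m] + eps,

with protein baselines mu_i ~ N(0, baseline_sd^2), per-experiment
organelle shifts delta_e ~ N(0, tau^2), analogous shifts for each extra
background module, and SILAC-like noise eps ~ N(0, sigma^2), all in log2
units.  Abundance is lognormal with the organelle's median scaled down
(the organelle is a low-abundance contaminant), and missingness is
either abundance-linked (logistic in log abundance, low-abundance
proteins drop out more, calibrated to the requested mean rate) or
missing completely at random for calibration work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .matrix_io import RatioMatrix


@dataclass
class SimulationParams:
    """Generator settings; defaults are the desk-scale study conditions.

    shift_sd (tau) and noise_sd (sigma) are log2 units; a tau comparable
    to sigma means each single experiment separates the organelle only
    weakly, as in real data.  abundance_ratio 0.1 makes the organelle
    an order of magnitude less abundant than the background.
    """

    n_proteins: int = 2000
    n_experiments: int = 45
    organelle_fraction: float = 0.08
    shift_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_sd: float = 0.2
    missing_rate: float = 0.35
    abundance_ratio: float = 0.1
    n_extra_modules: int = 2
    missing_mode: str = "abundance"   # or "mcar"
    min_obs: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.organelle_fraction < 1:
            raise ValueError("organelle_fraction must be in (0, 1)")
        for name in ("shift_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_mode not in ("abundance", "mcar"):
            raise ValueError("missing_mode must be 'abundance' or 'mcar'")
        if self.missing_rate >= 1 - self.min_obs / self.n_experiments:
            raise ValueError(
                f"infeasible missingness: missing_rate={self.missing_rate} >= "
                f"1 - min_obs/n_experiments = {1 - self.min_obs / self.n_experiments:.3f}"
            )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SyntheticTruth:
    """Planted labels and shifts of a simulated dataset."""

    labels: dict[str, str]                 # id -> organelle | module_<i> | background
    shifts: np.ndarray                     # per-experiment organelle shift, log2
    module_shifts: np.ndarray              # (n_extra_modules, n_experiments)
    n_dropped: int = 0                     # rows removed by the min_obs filter

    def organelle_ids(self) -> set[str]:
        return {p for p, l in self.labels.items() if l == "organelle"}

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"protein_id": list(self.labels), "label": list(self.labels.values())}
        ).to_csv(path, sep="\t", index=False)


def simulate_dataset(p: SimulationParams) -> tuple[RatioMatrix, SyntheticTruth]:
    """Generate one matrix plus its ground truth, fully seed-deterministic.

    Rows left with fewer than p.min_obs observed cells after the missing
    mask are dropped (mirroring the real pipeline's entry filter) and
    counted in the returned truth.
    """
    rng = np.random.default_rng(p.seed)
    n, ne = p.n_proteins, p.n_experiments
    ids = [f"P{i:06d}" for i in range(n)]

    n_org = int(round(p.organelle_fraction * n))
    perm = rng.permutation(n)
    org_rows = perm[:n_org]
    labels = np.array(["background"] * n, dtype=object)
    labels[org_rows] = "organelle"
    module_rows = []
    pos = n_org
    for mi in range(p.n_extra_modules):
        rows = perm[pos : pos + n_org]
        labels[rows] = f"module_{mi + 1}"
        module_rows.append(rows)
        pos += n_org

    mu = rng.normal(0.0, p.baseline_sd, size=n)
    delta = rng.normal(0.0, p.shift_sd, size=ne)
    module_delta = rng.normal(0.0, p.shift_sd, size=(p.n_extra_modules, ne))
    X = mu[:, None] + rng.normal(0.0, p.noise_sd, size=(n, ne))
    X[org_rows] += delta
    for mi, rows in enumerate(module_rows):
        X[rows] += module_delta[mi]

    # lognormal abundance; organelle median scaled by abundance_ratio
    ln_ab = rng.normal(np.log(1e6), 1.0, size=n)
    ln_ab[org_rows] += np.log(p.abundance_ratio)
    abundance = np.exp(ln_ab)

    if p.missing_rate > 0:
        if p.missing_mode == "mcar":
            p_miss = np.full(n, p.missing_rate)
        else:
            # logistic dropout in standardized log abundance, intercept
            # calibrated so the mean per-protein rate hits missing_rate
            z = (ln_ab - ln_ab.mean()) / ln_ab.std()
            a = brentq(
                lambda a0: expit(a0 - z).mean() - p.missing_rate, -30.0, 30.0
            )
            p_miss = expit(a - z)
        mask = rng.random(size=(n, ne)) < p_miss[:, None]
        X[mask] = np.nan

    observed = (~np.isnan(X)).sum(axis=1)
    keep = observed >= p.min_obs
    n_dropped = int((~keep).sum())

    matrix = RatioMatrix(
        [ids[i] for i in np.flatnonzero(keep)],
        [f"exp{e + 1:02d}" for e in range(ne)],
        X[keep],
        abundance=abundance[keep],
    )
    truth = SyntheticTruth(
        labels={ids[i]: labels[i] for i in np.flatnonzero(keep)},
        shifts=delta,
        module_shifts=module_delta,
        n_dropped=n_dropped,
    )
    return matrix, truth


def truth_catalog(truth: SyntheticTruth, target_label: str = "organelle"):
    """AnnotationCatalog view of the truth (score 5 for organelle members)."""
    from .matrix_io import AnnotationCatalog, CatalogEntry

    entries = {
        pid: CatalogEntry(locations={lab}, annotation_score=5)
        for pid, lab in truth.labels.items()
    }
    return AnnotationCatalog(entries=entries, source="synthetic_truth")


def evaluate_recovery(scores, truth: SyntheticTruth) -> tuple[float, float, float]:
    """How well the ensemble recovers the planted organelle.

    Returns (auc, recall_at_fp10, threshold): AUC of the mean score
    against the organelle labels, and the fraction of planted organelle
    proteins recovered at the smallest score threshold keeping the
    false-positive share of the selection at or below 10%.  When no
    threshold qualifies the recall is 0 and the threshold +inf.
    """
    from .evaluation import roc_auc

    org = truth.organelle_ids()
    y = np.array([pid in org for pid in scores.protein_ids])
    if not y.any():
        raise ValueError("no organelle proteins among the scored ids")
    s = scores.mean_score
    auc = roc_auc(s, y).auc

    order = np.argsort(-s, kind="mergesort")
    tp = np.cumsum(y[order])
    sel = np.arange(1, len(s) + 1)
    fp_frac = (sel - tp) / sel
    s_sorted = s[order]
    # consider only the last index of each tied score block
    block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    ok = (fp_frac <= 0.10) & block_end
    if not ok.any():
        return float(auc), 0.0, float("inf")
    i = np.flatnonzero(ok)[-1]          # smallest qualifying threshold
    recall = tp[i] / y.sum()
    return float(auc), float(recall), float(s_sorted[i])
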