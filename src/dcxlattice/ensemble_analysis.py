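"""Ensemble filtering, clustering, precision, crosslink satisfaction, densities.

All RMSDs are computed in the fixed-lattice frame without superposition: the
microtubule never moves during sampling, so every model shares the same frame
and positional differences are directly meaningful.

Sampling precision follows the standard exhaustiveness protocol: the runs are
split into two independent halves, the pooled ensemble is clustered at each
threshold on a grid, and the precision is the smallest threshold at which the
two halves populate the clusters indistinguishably (chi-squared homogeneity
p > 0.05, Cramer's V < 0.10, and at least 80% of models in clusters containing
members of both halves).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .restraints import CrosslinkSet, DensityMap
from .sampling import Ensemble
from .topology import LatticePatch


def pairwise_rmsd(config_a: np.ndarray, config_b: np.ndarray,
                  selection: Optional[np.ndarray] = None) -> float:
    """RMSD over selected bead centers, no superposition."""
    a = np.asarray(config_a, float)
    b = np.asarray(config_b, float)
    if selection is not None:
        a, b = a[selection], b[selection]
    if a.shape != b.shape:
        raise ValueError("configurations differ in selected bead count")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _rmsd_matrix(stack: np.ndarray) -> np.ndarray:
    diff = stack[:, None, :, :] - stack[None, :, :, :]
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=-1), axis=-1))


@dataclass
class Cluster:
    members: list[int]           # indices into the analyzed model list
    centroid: int                # member with minimum mean RMSD to members
    population: float            # fraction of analyzed models
    precision: float             # mean member RMSD to the centroid model (A)


def filter_models(ensemble: Ensemble, patch: Optional[LatticePatch],
                  mobile_selection: np.ndarray,
                  score_quantile: float = 0.5) -> tuple[Ensemble, np.ndarray]:
    """Keep the best ``score_quantile`` of models whose mobile-domain centroid
    sits nearest an interior lattice junction (edge binding sites, where more
    tubulin would sit in a full microtubule, are artifacts of the finite patch).

    Returns the filtered ensemble and the indices kept.
    """
    scores = ensemble.scores
    cut = np.quantile(scores, score_quantile)
    keep = []
    for i, m in enumerate(ensemble.models):
        if scores[i] > cut:
            continue
        if patch is not None:
            centroid = m.coords[mobile_selection].mean(axis=0)
            if not patch.nearest_junction(centroid).interior:
                continue
        keep.append(i)
    return ensemble.subset(keep), np.array(keep, int)


def cluster_models(coords_stack: np.ndarray, scores: np.ndarray,
                   threshold: float,
                   selection: Optional[np.ndarray] = None) -> list[Cluster]:
    """Leader clustering on score-sorted models.

    Models are visited best-score first; each joins the first cluster whose
    founding model is within ``threshold`` RMSD, else founds a new cluster.
    Centroids are recomputed once at the end (member with minimal mean RMSD to
    the other members); clusters are sorted by population.
    """
    sel = coords_stack if selection is None else coords_stack[:, selection, :]
    order = np.argsort(scores, kind="stable")
    leaders: list[int] = []
    assignment: dict[int, list[int]] = {}
    for i in order:
        placed = False
        for k, lead in enumerate(leaders):
            if pairwise_rmsd(sel[i], sel[lead]) <= threshold:
                assignment[k].append(int(i))
                placed = True
                break
        if not placed:
            leaders.append(int(i))
            assignment[len(leaders) - 1] = [int(i)]
    n = len(scores)
    clusters = []
    for k, members in assignment.items():
        sub = sel[members]
        dm = _rmsd_matrix(sub)
        mean_rmsd = dm.mean(axis=1)
        c_local = int(np.argmin(mean_rmsd))
        precision = float(dm[c_local].mean())
        clusters.append(Cluster(members=members, centroid=members[c_local],
                                population=len(members) / n, precision=precision))
    clusters.sort(key=lambda c: -c.population)
    return clusters


def sampling_precision(coords_stack: np.ndarray, scores: np.ndarray,
                       run_labels: np.ndarray, threshold_grid: Sequence[float],
                       selection: Optional[np.ndarray] = None,
                       p_min: float = 0.05, v_max: float = 0.10,
                       both_frac: float = 0.80) -> tuple[float, pd.DataFrame]:
    """Smallest clustering threshold at which two independent halves of the
    runs give statistically indistinguishable cluster populations.

    Returns (precision, per-threshold test table). Precision is inf when no
    grid threshold passes.
    """
    runs = np.unique(run_labels)
    if len(runs) < 2:
        raise ValueError("sampling precision needs at least 2 independent runs")
    half_a = set(runs[: len(runs) // 2])
    in_a = np.array([r in half_a for r in run_labels])
    rows = []
    precision = float("inf")
    for thr in sorted(threshold_grid):
        clusters = cluster_models(coords_stack, scores, thr, selection)
        table = np.array([
            [np.sum(in_a[c.members]), np.sum(~in_a[c.members])] for c in clusters
        ])
        n = table.sum()
        if len(clusters) == 1:
            p, v = 1.0, 0.0
        else:
            # chi-squared homogeneity of the A/B population profiles
            chi2 = stats.chi2_contingency(table.T + 1e-9, correction=False)[0]
            p = stats.chi2.sf(chi2, df=len(clusters) - 1)
            v = float(np.sqrt(chi2 / n))
        both = sum(len(c.members) for c, t in zip(clusters, table)
                   if t[0] > 0 and t[1] > 0) / n
        passed = (p > p_min) and (v < v_max) and (both >= both_frac)
        rows.append({"threshold": thr, "n_clusters": len(clusters), "p_value": p,
                     "cramers_v": v, "frac_in_shared_clusters": both,
                     "passed": passed})
        if passed and thr < precision:
            precision = thr
    return precision, pd.DataFrame(rows)


@dataclass
class SatisfactionReport:
    per_model: np.ndarray                  # fraction satisfied, per model
    min_distances: np.ndarray              # (n_models, n_xl) minimum assignment distance
    crosslink_ids: list[str]
    thresholds: np.ndarray                 # per crosslink (35 LC-SDA/DSS, 30 EDC)
    per_cluster: dict[int, float] = field(default_factory=dict)

    def satisfied(self) -> np.ndarray:
        """Boolean (n_models, n_xl); strict less-than per the threshold rule."""
        return self.min_distances < self.thresholds[None, :]

    def table(self) -> pd.DataFrame:
        best = self.min_distances.min(axis=0)
        return pd.DataFrame({
            "crosslink": self.crosslink_ids,
            "threshold_A": self.thresholds,
            "min_distance_A": best,
            "satisfied_any_model": best < self.thresholds,
        })


def crosslink_satisfaction(ensemble: Ensemble, xls: CrosslinkSet, topology,
                           clusters: Optional[list[Cluster]] = None) -> SatisfactionReport:
    """Per-model and per-cluster satisfaction fractions.

    A crosslink is satisfied in a model if its minimum assignment distance is
    strictly below the chemistry threshold; a cluster satisfies a crosslink if
    at least one member does.
    """
    from .restraints import _CompiledCrosslinks

    comp = _CompiledCrosslinks(xls, topology)
    mins = np.stack([comp.min_distances(m.coords) for m in ensemble.models])
    thr = comp.thresholds
    sat = mins < thr[None, :]
    report = SatisfactionReport(
        per_model=sat.mean(axis=1),
        min_distances=mins,
        crosslink_ids=[xl.id for xl in xls],
        thresholds=thr,
    )
    if clusters is not None:
        for k, c in enumerate(clusters):
            report.per_cluster[k] = float(sat[c.members].any(axis=0).mean())
    return report


def localization_density(ensemble: Ensemble, members: Sequence[int],
                         component_beads: np.ndarray, radii: np.ndarray,
                         masses: np.ndarray, voxel: float = 2.0,
                         padding: float = 12.0) -> DensityMap:
    """Gaussian-splatted occupancy of a component over a cluster's members.

    The map integrates to the component's total mass (the per-model mass,
    averaged over members).
    """
    pts = np.concatenate([ensemble.models[i].coords[component_beads] for i in members])
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 4)
    data = np.zeros(shape)
    axes = [lo[k] + voxel * np.arange(shape[k]) for k in range(3)]
    for i in members:
        coords = ensemble.models[i].coords[component_beads]
        for c, r, m in zip(coords, radii, masses):
            _splat(data, axes, c, r, m / len(members), voxel)
    return DensityMap(data, voxel, lo)


def _splat(data: np.ndarray, axes, center: np.ndarray, sigma: float,
           mass: float, voxel: float, cutoff: float = 4.0) -> None:
    sl, gs = [], []
    for k in range(3):
        ax = axes[k]
        m = np.abs(ax - center[k]) <= cutoff * sigma
        idx = np.nonzero(m)[0]
        if len(idx) == 0:
            return
        sl.append(slice(idx[0], idx[-1] + 1))
        gs.append(np.exp(-0.5 * ((ax[idx] - center[k]) / sigma) ** 2))
    g = gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
    norm = mass / ((2 * np.pi) ** 1.5 * sigma ** 3)
    data[sl[0], sl[1], sl[2]] += norm * g
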