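"""Bayesian crosslink, excluded-volume, connectivity, and EM-density restraints.

The total score of a configuration is the sum of four terms:

* crosslink: a two-state mixture score per crosslink. Each admissible
  assignment (site x copy on both ends) at distance d is satisfied with
  probability p(d) = 1/(1 + exp((d - d0)/lam)); the restraint probability is
  the joint P = 1 - prod(1 - p) over assignments, and the score is
  -log((1 - psi) P + psi (1 - P)), so an unsatisfiable crosslink costs at most
  -log(psi).
* excluded volume: half-harmonic overlap penalty on the 10-residue scoring
  beads, (k/2) max(0, r_i + r_j - d)^2 per pair.
* connectivity: harmonic upper bound on sequence-adjacent beads with center
  c = 2 (r_i + r_j).
* EM: w_em (1 - cc) where cc is the Gaussian-mixture cross-correlation of the
  mobile-domain density against the (microtubule-erased) experimental density.

Restraint distances d0 are 30 A for LC-SDA and DSS and 25 A for EDC;
post-hoc satisfaction thresholds are 35 and 30 A respectively.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .topology import Topology

CHEMISTRIES = ("LCSDA", "DSS", "EDC")
RESTRAINT_D0 = {"LCSDA": 30.0, "DSS": 30.0, "EDC": 25.0}
SATISFACTION_THRESHOLD = {"LCSDA": 35.0, "DSS": 35.0, "EDC": 30.0}


@dataclass
class Crosslink:
    id: str
    protein1: str
    sites1: frozenset[int]
    protein2: str
    sites2: frozenset[int]
    chemistry: str
    copies1: Optional[frozenset[str]] = None  # chain ids; None = all copies of the entity
    copies2: Optional[frozenset[str]] = None
    inter_copy_only: bool = False  # doublet-called interprotein link: the two
    # ends must sit on different chain copies
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if not self.sites1 or not self.sites2:
            raise ValueError(f"crosslink {self.id}: empty site set")

    @property
    def d0(self) -> float:
        return RESTRAINT_D0[self.chemistry]

    @property
    def threshold(self) -> float:
        return SATISFACTION_THRESHOLD[self.chemistry]


@dataclass
class CrosslinkSet:
    links: list[Crosslink]

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)

    def to_csv(self, path: str | Path | io.IOBase) -> None:
        rows = []
        for xl in self.links:
            rows.append({
                "id": xl.id,
                "protein1": xl.protein1,
                "sites1": "|".join(str(s) for s in sorted(xl.sites1)),
                "protein2": xl.protein2,
                "sites2": "|".join(str(s) for s in sorted(xl.sites2)),
                "chemistry": xl.chemistry,
                "copies1": "|".join(sorted(xl.copies1)) if xl.copies1 else "",
                "copies2": "|".join(sorted(xl.copies2)) if xl.copies2 else "",
                "inter_copy_only": int(xl.inter_copy_only),
                "is_decoy": int(xl.is_decoy),
            })
        pd.DataFrame(rows).to_csv(path, index=False)

    @staticmethod
    def from_csv(path: str | Path | io.IOBase) -> "CrosslinkSet":
        df = pd.read_csv(path, dtype={"copies1": str, "copies2": str})
        links = []
        for _, r in df.iterrows():
            links.append(Crosslink(
                id=str(r["id"]),
                protein1=str(r["protein1"]),
                sites1=frozenset(int(s) for s in str(r["sites1"]).split("|")),
                protein2=str(r["protein2"]),
                sites2=frozenset(int(s) for s in str(r["sites2"]).split("|")),
                chemistry=str(r["chemistry"]),
                copies1=frozenset(str(r["copies1"]).split("|"))
                if "copies1" in df and isinstance(r.get("copies1"), str) and r["copies1"] else None,
                copies2=frozenset(str(r["copies2"]).split("|"))
                if "copies2" in df and isinstance(r.get("copies2"), str) and r["copies2"] else None,
                inter_copy_only=bool(int(r["inter_copy_only"]))
                if "inter_copy_only" in df else False,
                is_decoy=bool(int(r["is_decoy"])) if "is_decoy" in df else False,
            ))
        return CrosslinkSet(links)

    @property
    def true_links(self) -> "CrosslinkSet":
        return CrosslinkSet([x for x in self.links if not x.is_decoy])

    @property
    def decoys(self) -> "CrosslinkSet":
        return CrosslinkSet([x for x in self.links if x.is_decoy])


@dataclass
class RestraintParams:
    psi: float = 0.05        # restraint uncertainty (mixture weight)
    lam: float = 2.0         # logistic softness, A
    k_ev: float = 1.0        # excluded-volume stiffness, 1/A^2
    k_conn: float = 1.0      # connectivity stiffness, 1/A^2
    w_em: float = 100.0      # EM term weight

    def __post_init__(self) -> None:
        if not (0.0 <= self.psi <= 0.5):
            raise ValueError("psi must lie in [0, 0.5]")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


# ---------------------------------------------------------------------------
# crosslink resolution and score

def resolve_crosslink(xl: Crosslink, topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """Bead indices admissible for each end (site x copy ambiguity)."""
    out = []
    for protein, sites, copies in ((xl.protein1, xl.sites1, xl.copies1),
                                   (xl.protein2, xl.sites2, xl.copies2)):
        chains = sorted(copies) if copies else topology.chains_of_entity(protein)
        beads = set()
        for cid in chains:
            for s in sites:
                try:
                    beads.add(topology.site_bead(cid, s))
                except KeyError:
                    continue
        if not beads:
            raise ValueError(f"crosslink {xl.id}: no resolvable site for {protein} {sorted(sites)}")
        out.append(np.array(sorted(beads), int))
    return out[0], out[1]


class _CompiledCrosslinks:
    """Flat pair-index arrays so the score is a single vectorized pass."""

    def __init__(self, xls: CrosslinkSet, topology: Topology):
        self.xls = xls
        I, J, owner, d0s = [], [], [], []
        self.n = len(xls)
        beads = topology.all_beads
        for k, xl in enumerate(xls):
            b1, b2 = resolve_crosslink(xl, topology)
            if xl.inter_copy_only:
                pairs = [(i, j) for i in b1 for j in b2
                         if beads[i].chain_id != beads[j].chain_id]
            else:
                pairs = [(i, j) for i in b1 for j in b2 if i != j]
            if not pairs:
                raise ValueError(f"crosslink {xl.id}: only degenerate self-assignments")
            for i, j in pairs:
                I.append(i)
                J.append(j)
                owner.append(k)
            d0s.append(xl.d0)
        self.I = np.array(I, int)
        self.J = np.array(J, int)
        self.owner = np.array(owner, int)
        self.d0 = np.array(d0s, float)
        self.thresholds = np.array([xl.threshold for xl in xls], float)

    def distances(self, coords: np.ndarray) -> np.ndarray:
        return np.linalg.norm(coords[self.I] - coords[self.J], axis=1)

    def score(self, coords: np.ndarray, params: RestraintParams) -> float:
        d = self.distances(coords)
        z = (d - self.d0[self.owner]) / params.lam
        # log(1 - p) for p = 1/(1+e^z) is -log(1 + e^-z); stable for both signs
        log1mp = -np.logaddexp(0.0, -z)
        acc = np.zeros(self.n)
        np.add.at(acc, self.owner, log1mp)
        P = -np.expm1(acc)  # 1 - prod(1 - p)
        mix = (1.0 - params.psi) * P + params.psi * (1.0 - P)
        return float(-np.log(np.maximum(mix, 1e-300)).sum())

    def min_distances(self, coords: np.ndarray) -> np.ndarray:
        """Per-crosslink minimum assignment distance (for satisfaction calls)."""
        d = self.distances(coords)
        out = np.full(self.n, np.inf)
        np.minimum.at(out, self.owner, d)
        return out


def crosslink_score(coords: np.ndarray, xls: CrosslinkSet, topology: Topology,
                    params: RestraintParams) -> float:
    """-log posterior of the crosslink set given bead coordinates ``coords``."""
    return _CompiledCrosslinks(xls, topology).score(np.asarray(coords, float), params)


# ---------------------------------------------------------------------------
# physical terms

def _ev_pairs(topology: Topology) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = topology.scoring_indices
    bonds = {frozenset(p) for p in topology.bonded_pairs}
    I, J = [], []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = int(idx[a]), int(idx[b])
            rbi, rbj = topology.rigid_body_of(i), topology.rigid_body_of(j)
            if rbi is not None and rbi == rbj:
                continue
            if frozenset((i, j)) in bonds:
                continue
            I.append(i)
            J.append(j)
    radii = {b.id: b.radius for b in topology.beads}
    rsum = np.array([radii[i] + radii[j] for i, j in zip(I, J)])
    return np.array(I, int), np.array(J, int), rsum


def excluded_volume_score(coords: np.ndarray, topology: Topology,
                          k_ev: float = 1.0) -> float:
    I, J, rsum = _ev_pairs(topology)
    if len(I) == 0:
        return 0.0
    d = np.linalg.norm(coords[I] - coords[J], axis=1)
    return float(0.5 * k_ev * np.sum(np.maximum(0.0, rsum - d) ** 2))


def connectivity_score(coords: np.ndarray, topology: Topology,
                       k_conn: float = 1.0) -> float:
    total = 0.0
    radii = {b.id: b.radius for b in topology.all_beads}
    for i, j in topology.bonded_pairs:
        c = 2.0 * (radii[i] + radii[j])
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > c:
            total += 0.5 * k_conn * (d - c) ** 2
    return total


# ---------------------------------------------------------------------------
# Gaussian mixtures and the EM term

@dataclass
class GMM:
    weights: np.ndarray            # (n,)
    means: np.ndarray              # (n, 3)
    covariances: np.ndarray        # (n, 3, 3), SPD
    normalized: bool = False       # True if weights sum to 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float).reshape(-1)
        self.means = np.asarray(self.means, float).reshape(-1, 3)
        self.covariances = np.asarray(self.covariances, float).reshape(-1, 3, 3)
        if np.any(self.weights < 0):
            raise ValueError("GMM weights must be non-negative")
        for c in self.covariances:
            if not np.allclose(c, c.T, atol=1e-8) or np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("GMM covariances must be symmetric positive-definite")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def to_table(self, path: str | Path) -> None:
        cols = {"weight": self.weights}
        for k, ax in enumerate("xyz"):
            cols[f"mean_{ax}"] = self.means[:, k]
        for a in range(3):
            for b in range(3):
                cols[f"cov_{'xyz'[a]}{'xyz'[b]}"] = self.covariances[:, a, b]
        pd.DataFrame(cols).to_csv(path, index=False)

    @staticmethod
    def from_table(path: str | Path) -> "GMM":
        df = pd.read_csv(path)
        means = df[[f"mean_{ax}" for ax in "xyz"]].to_numpy()
        covs = np.stack([
            df[[f"cov_{'xyz'[a]}{'xyz'[b]}" for b in range(3)]].to_numpy()
            for a in range(3)
        ], axis=1)
        return GMM(df["weight"].to_numpy(), means, covs)


def beads_to_gmm(centers: np.ndarray, radii: np.ndarray, masses: np.ndarray) -> GMM:
    """One isotropic component per bead: weight = mass, variance = radius^2."""
    centers = np.asarray(centers, float).reshape(-1, 3)
    radii = np.asarray(radii, float).reshape(-1)
    covs = np.einsum("i,jk->ijk", radii ** 2, np.eye(3))
    return GMM(np.asarray(masses, float), centers, covs)


def gmm_overlap(f: GMM, g: GMM) -> float:
    """Closed-form integral of f*g over R^3 (sum over component pairs)."""
    S = f.covariances[:, None, :, :] + g.covariances[None, :, :, :]
    mu = f.means[:, None, :] - g.means[None, :, :]
    det = np.linalg.det(S)
    Sinv = np.linalg.inv(S)
    quad = np.einsum("ijk,ijkl,ijl->ij", mu, Sinv, mu)
    norm = (2.0 * np.pi) ** -1.5 / np.sqrt(det)
    w = f.weights[:, None] * g.weights[None, :]
    return float(np.sum(w * norm * np.exp(-0.5 * quad)))


def em_cross_correlation(model_gmm: GMM, data_gmm: GMM) -> float:
    omd = gmm_overlap(model_gmm, data_gmm)
    omm = gmm_overlap(model_gmm, model_gmm)
    odd = gmm_overlap(data_gmm, data_gmm)
    return float(omd / np.sqrt(omm * odd))


def em_score(model_gmm: GMM, data_gmm: GMM, params: RestraintParams) -> float:
    return params.w_em * (1.0 - em_cross_correlation(model_gmm, data_gmm))


# ---------------------------------------------------------------------------
# density maps (MRC/CCP4 via gemmi)

@dataclass
class DensityMap:
    """Node-centered voxel grid: voxel (i,j,k) sits at origin + voxel_size*(i,j,k)."""
    data: np.ndarray       # (nx, ny, nz)
    voxel_size: float      # A
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.data.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
        return pts * self.voxel_size + self.origin

    def integral(self) -> float:
        return float(self.data.sum() * self.voxel_size ** 3)

    def write_mrc(self, path: str | Path) -> None:
        import gemmi
        nx, ny, nz = self.data.shape
        grid = gemmi.FloatGrid(nx, ny, nz)
        grid.spacegroup = gemmi.SpaceGroup("P1")
        grid.set_unit_cell(gemmi.UnitCell(nx * self.voxel_size, ny * self.voxel_size,
                                          nz * self.voxel_size, 90, 90, 90))
        arr = np.array(grid, copy=False)
        arr[...] = self.data.astype(np.float32)
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        for w, v in zip((50, 51, 52), self.origin):
            m.set_header_float(w, float(v))
        m.write_ccp4_map(str(path))

    @staticmethod
    def read_mrc(path: str | Path) -> "DensityMap":
        import gemmi
        m = gemmi.read_ccp4_map(str(path))
        data = np.array(m.grid, copy=True).astype(float)
        voxel = m.grid.unit_cell.a / m.grid.nu
        origin = np.array([m.header_float(w) for w in (50, 51, 52)])
        return DensityMap(data, voxel, origin)


def robust_noise_floor(data: np.ndarray, k: float = 3.0) -> float:
    """k times the MAD-based noise scale of the map values."""
    med = np.median(data)
    mad = np.median(np.abs(data - med))
    return float(med + k * 1.4826 * mad)


def fit_map_gmm(density: DensityMap, n_components: int, seed: int,
                floor: Optional[float] = None, n_samples: int = 4000) -> GMM:
    """EM fit of a GMM to a density map.

    Voxels above the floor (default: 3x the map's robust noise level) are
    sampled with probability proportional to density and jittered within their
    voxel, then fitted with scikit-learn's GaussianMixture. Deterministic for
    a fixed seed.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    from sklearn.mixture import GaussianMixture

    if floor is None:
        floor = robust_noise_floor(density.data)
    vals = density.data.reshape(-1)
    mask = vals > floor
    if not mask.any():
        raise ValueError("density map empty after flooring")
    centers = density.voxel_centers()[mask]
    w = vals[mask]
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(w), size=n_samples, replace=True, p=w / w.sum())
    pts = centers[idx] + rng.uniform(-0.5, 0.5, size=(n_samples, 3)) * density.voxel_size
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         random_state=int(seed) % (2 ** 31), n_init=3, reg_covar=1e-3)
    gm.fit(pts)
    return GMM(gm.weights_, gm.means_, gm.covariances_, normalized=True)


# ---------------------------------------------------------------------------
# the assembled scoring system

class ScoringSystem:
    """Topology + restraints compiled into a fast ``score(coords)`` callable.

    ``em_selection`` names the scoring-bead indices whose isotropic GMM is
    compared against ``data_gmm`` (normally the mobile domain, since the
    microtubule contribution is erased from the experimental map).
    """

    def __init__(self, topology: Topology, xls: Optional[CrosslinkSet] = None,
                 params: Optional[RestraintParams] = None,
                 data_gmm: Optional[GMM] = None,
                 em_selection: Optional[np.ndarray] = None):
        self.topology = topology
        self.params = params or RestraintParams()
        self.xls = xls
        self._xl = _CompiledCrosslinks(xls, topology) if xls is not None and len(xls) else None
        self._ev_I, self._ev_J, self._ev_rsum = _ev_pairs(topology)
        radii = {b.id: b.radius for b in topology.all_beads}
        conn = [(i, j, 2.0 * (radii[i] + radii[j]))
                for i, j in topology.bonded_pairs]
        self._conn = (np.array([c[0] for c in conn], int),
                      np.array([c[1] for c in conn], int),
                      np.array([c[2] for c in conn], float))
        self.data_gmm = data_gmm
        if data_gmm is not None:
            if em_selection is None:
                raise ValueError("EM restraint requires an em_selection")
            self._em_idx = np.asarray(em_selection, int)
            beads = topology.all_beads
            self._em_radii = np.array([beads[i].radius for i in self._em_idx])
            self._em_masses = np.array([beads[i].mass for i in self._em_idx])

    def score(self, coords: np.ndarray) -> tuple[float, dict[str, float]]:
        terms: dict[str, float] = {}
        if self._xl is not None:
            terms["crosslink"] = self._xl.score(coords, self.params)
        d = np.linalg.norm(coords[self._ev_I] - coords[self._ev_J], axis=1) \
            if len(self._ev_I) else np.zeros(0)
        terms["excluded_volume"] = float(
            0.5 * self.params.k_ev * np.sum(np.maximum(0.0, self._ev_rsum - d) ** 2))
        ci, cj, cc = self._conn
        if len(ci):
            dc = np.linalg.norm(coords[ci] - coords[cj], axis=1)
            terms["connectivity"] = float(
                0.5 * self.params.k_conn * np.sum(np.maximum(0.0, dc - cc) ** 2))
        else:
            terms["connectivity"] = 0.0
        if self.data_gmm is not None:
            mg = beads_to_gmm(coords[self._em_idx], self._em_radii, self._em_masses)
            terms["em"] = em_score(mg, self.data_gmm, self.params)
        return float(sum(terms.values())), terms

    def crosslink_min_distances(self, coords: np.ndarray) -> np.ndarray:
        if self._xl is None:
            return np.zeros(0)
        return self._xl.min_distances(coords)


def total_score(coords: np.ndarray, system: ScoringSystem) -> tuple[float, dict[str, float]]:
    """Sum of the four restraint terms, with the per-term breakdown."""
    return system.score(np.asarray(coords, float))
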