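"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study's inputs at toy scale: a planar patch of
pseudo-tubulin monomers on the B-lattice grid (lateral spacing ~52 A,
longitudinal dimer repeat ~82 A), a mobile domain docked at a junction,
crosslink tables drawn from surface pairs within the chemistry length (plus a
controllable decoy fraction), Gaussian-splatted density maps of the true pose,
and MS1 envelopes of the four 14N/15N crosslinked species. Every generator is
a pure function of (parameters, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import RigidTransform, random_rotation_uniform
from .restraints import (RESTRAINT_D0, Crosslink, CrosslinkSet, DensityMap)
from .topology import (Chain, ChainSet, LatticePatch, Residue, build_lattice_patch)
from . import isotope_doublet as iso

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STEP = 3.8          # Calpha-Calpha distance, A
_MIN_SEP = 3.6       # self-avoidance, A


@dataclass
class GroundTruth:
    """True poses and bookkeeping recorded alongside every generated dataset."""
    poses: dict[str, RigidTransform] = field(default_factory=dict)
    true_junction: Optional[tuple[int, int]] = None
    decoy_ids: list[str] = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)


def _self_avoiding_blob(n_residues: int, radius: float, rng: np.random.Generator,
                        elongation: float = 1.0) -> np.ndarray:
    """Compact self-avoiding Calpha walk inside an ellipsoid, centered at its
    centroid so replicated copies land exactly on the lattice grid."""
    semi = np.array([radius * elongation, radius, radius])
    for _ in range(200):  # restart if the walk jams
        pts = [np.zeros(3)]
        ok = True
        for _i in range(n_residues - 1):
            placed = False
            for _try in range(300):
                v = rng.normal(size=3)
                v *= _STEP / np.linalg.norm(v)
                cand = pts[-1] + v
                if np.sum((cand / semi) ** 2) > 1.0:
                    continue
                if len(pts) > 1:
                    d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
                    if d.min() < _MIN_SEP:
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            arr = np.array(pts)
            return arr - arr.mean(axis=0)
    raise RuntimeError("could not generate a self-avoiding blob; increase radius")


def make_toy_domain(n_residues: int, seed: int, chain_id: str = "X",
                    entity: str = "ndc", radius: Optional[float] = None,
                    elongation: float = 1.0) -> Chain:
    """A compact pseudo-domain: self-avoiding Calpha blob, centroid at origin."""
    rng = np.random.default_rng(seed)
    if radius is None:
        # 30% looser than the close-packed equal-volume sphere
        radius = 1.3 * (3.0 * n_residues * 135.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    xyz = _self_avoiding_blob(n_residues, radius, rng, elongation)
    aas = rng.choice(list(_AA), size=n_residues)
    residues = [Residue(i + 1, a, x) for i, (a, x) in enumerate(zip(aas, xyz))]
    return Chain(chain_id, entity, residues)


def make_toy_lattice(n_protofilaments: int = 3, n_dimers: int = 3,
                     monomer_n_residues: int = 40, seed: int = 0,
                     lateral_spacing: float = 52.0,
                     longitudinal_spacing: float = 82.0,
                     monomer_radius: float = 17.0) -> tuple[ChainSet, LatticePatch]:
    """Planar pseudo-tubulin patch: one alpha and one beta blob replicated on
    the (protofilament, dimer) grid by pure translations."""
    ss = np.random.SeedSequence(seed).spawn(2)
    alpha = make_toy_domain(monomer_n_residues, int(ss[0].generate_state(1)[0] % 2**31),
                            chain_id="a", entity="alpha_tubulin", radius=monomer_radius)
    beta = make_toy_domain(monomer_n_residues, int(ss[1].generate_state(1)[0] % 2**31),
                           chain_id="b", entity="beta_tubulin", radius=monomer_radius)
    for r in beta.residues:  # beta sits half a dimer repeat along the protofilament
        r.ca_xyz = r.ca_xyz + np.array([0.0, longitudinal_spacing / 2.0, 0.0])
    dimer = ChainSet([alpha, beta])
    return build_lattice_patch(
        dimer, n_protofilaments, n_dimers,
        lateral_T=RigidTransform.translation_only([lateral_spacing, 0.0, 0.0]),
        longitudinal_T=RigidTransform.translation_only([0.0, longitudinal_spacing, 0.0]),
    )


def place_chain(chain: Chain, pose: RigidTransform, chain_id: Optional[str] = None) -> Chain:
    """Copy of a chain with coordinates under a rigid transform."""
    return Chain(chain_id or chain.chain_id, chain.entity, [
        Residue(r.resnum, r.aa, pose.apply(r.ca_xyz) if r.ca_xyz is not None else None)
        for r in chain.residues
    ])


def simulate_crosslinks(side1: ChainSet, side2: ChainSet, n_true: int,
                        decoy_fraction: float = 0.0,
                        chemistry_mix: Optional[dict[str, float]] = None,
                        seed: int = 0, site_ambiguity: int = 0,
                        restrict1: Optional[tuple[int, int]] = None,
                        restrict2: Optional[tuple[int, int]] = None,
                        copy_specific: tuple[bool, bool] = (False, False),
                        inter_copy_only: bool = False,
                        id_prefix: str = "xl") -> tuple[CrosslinkSet, GroundTruth]:
    """Crosslinks between two components in their ground-truth coordinates.

    True links are drawn uniformly from inter-component residue pairs whose
    true Calpha distance is below the chemistry restraint length d0; decoys
    (round(n_true * decoy_fraction) of them) are drawn from all pairs
    irrespective of distance and flagged. Optional positional ambiguity widens
    each site to +-``site_ambiguity`` residues.

    ``copy_specific`` controls, per end, whether the crosslink records the
    chain copy it was drawn on. With False the link is entity-level, so it is
    copy-ambiguous over every chain of that entity (the condition for the
    two-copy dimer scenarios); with True the copy is pinned, which emulates
    modeling against the minimal repeat unit where each tubulin position is
    distinguishable. ``inter_copy_only`` marks the links as doublet-confirmed
    interprotein, restricting assignments to different chain copies.
    """
    rng = np.random.default_rng(seed)
    chemistry_mix = chemistry_mix or {"LCSDA": 1.0}
    chems = sorted(chemistry_mix)
    probs = np.array([chemistry_mix[c] for c in chems], float)
    probs /= probs.sum()

    def residues_of(cs: ChainSet, restrict):
        out = []
        for ch in cs.chains:
            for r in ch.residues:
                if r.ca_xyz is None:
                    continue
                if restrict and not (restrict[0] <= r.resnum <= restrict[1]):
                    continue
                out.append((ch, r))
        return out

    r1 = residues_of(side1, restrict1)
    r2 = residues_of(side2, restrict2)
    x1 = np.array([r.ca_xyz for _, r in r1])
    x2 = np.array([r.ca_xyz for _, r in r2])
    dmat = np.linalg.norm(x1[:, None, :] - x2[None, :, :], axis=-1)
    same_chain = np.array([[c1.chain_id == c2.chain_id for c2, _ in r2] for c1, _ in r1])

    links: list[Crosslink] = []
    decoy_ids: list[str] = []

    def make_link(i: int, j: int, chem: str, decoy: bool, k: int) -> Crosslink:
        c1, res1 = r1[i]
        c2, res2 = r2[j]

        def widen(ch: Chain, resnum: int) -> frozenset[int]:
            nums = set(ch.resnums)
            return frozenset(n for n in range(resnum - site_ambiguity,
                                              resnum + site_ambiguity + 1) if n in nums)

        xid = f"{id_prefix}{'d' if decoy else ''}{k}"
        return Crosslink(xid, c1.entity, widen(c1, res1.resnum),
                         c2.entity, widen(c2, res2.resnum), chem,
                         copies1=frozenset([c1.chain_id]) if copy_specific[0] else None,
                         copies2=frozenset([c2.chain_id]) if copy_specific[1] else None,
                         inter_copy_only=inter_copy_only, is_decoy=decoy)

    chem_draws = rng.choice(len(chems), size=n_true, p=probs)
    for k in range(n_true):
        chem = chems[chem_draws[k]]
        ok = np.argwhere((dmat < RESTRAINT_D0[chem]) & ~same_chain)
        if len(ok) == 0:
            raise ValueError(f"no residue pairs within d0 for {chem}; "
                             "ground-truth pose is out of crosslinking range")
        i, j = ok[rng.integers(len(ok))]
        links.append(make_link(int(i), int(j), chem, False, k))
    n_decoy = round(n_true * decoy_fraction)
    all_pairs = np.argwhere(~same_chain)
    for k in range(n_decoy):
        chem = chems[int(rng.integers(len(chems)))] if len(chems) > 1 else chems[0]
        i, j = all_pairs[rng.integers(len(all_pairs))]
        xl = make_link(int(i), int(j), chem, True, k)
        links.append(xl)
        decoy_ids.append(xl.id)
    gt = GroundTruth(decoy_ids=decoy_ids, seed=seed,
                     params={"n_true": n_true, "decoy_fraction": decoy_fraction,
                             "chemistry_mix": chemistry_mix,
                             "site_ambiguity": site_ambiguity})
    return CrosslinkSet(links), gt


def simulate_density(centers: np.ndarray, radii: np.ndarray, masses: np.ndarray,
                     resolution: float = 8.0, noise_sd: float = 0.0, seed: int = 0,
                     voxel: float = 2.0, padding: float = 15.0) -> DensityMap:
    """Gaussian-splatted map of the mobile domain only (the lattice contributes
    zero density, mirroring a microtubule-erased experimental map), plus white
    noise. sigma per bead combines the bead radius with resolution/2.355."""
    from .ensemble_analysis import _splat

    centers = np.asarray(centers, float).reshape(-1, 3)
    lo = centers.min(axis=0) - padding
    hi = centers.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 4)
    data = np.zeros(shape)
    axes = [lo[k] + voxel * np.arange(shape[k]) for k in range(3)]
    sig_res = resolution / 2.355
    for c, r, m in zip(centers, np.asarray(radii, float), np.asarray(masses, float)):
        _splat(data, axes, c, float(np.hypot(r, sig_res)), float(m), voxel)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd * data.max(), size=data.shape)
    return DensityMap(data, voxel, lo)


def simulate_ms1(label: str, pep1: str = "LVSAIGEK", pep2: str = "NTFDAIMR",
                 chemistry: str = "LCSDA", charge: int = 3,
                 weights: Optional[dict[str, float]] = None,
                 noise_sd: float = 0.0, seed: int = 0,
                 enrichment: float = 0.99
                 ) -> tuple[iso.IsotopePattern, dict[str, iso.IsotopePattern]]:
    """Observed MS1 pattern for a crosslink of the given class, plus the four
    candidate species envelopes. Class defaults: intra 1:0:0:1, inter 1:1:1:1,
    mixed 2:1:1:2 (LL:LH:HL:HH)."""
    defaults = {"intra": {"LL": 1, "LH": 0, "HL": 0, "HH": 1},
                "inter": {"LL": 1, "LH": 1, "HL": 1, "HH": 1},
                "mixed": {"LL": 2, "LH": 1, "HL": 1, "HH": 2}}
    if weights is None:
        if label not in defaults:
            raise ValueError(f"unknown class {label!r}")
        weights = defaults[label]
    cands = iso.predict_species(pep1, pep2, chemistry, charge, enrichment=enrichment)
    obs = iso.mix_species(cands, weights)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = obs.intensity + rng.normal(0.0, noise_sd * obs.intensity.max(),
                                           size=obs.intensity.shape)
        obs = iso.IsotopePattern(obs.mz, np.clip(noisy, 0.0, None), obs.charge,
                                 species_weights=obs.species_weights)
    return obs, cands
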