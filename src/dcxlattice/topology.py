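"""Structures, coarse-grained representation, and microtubule lattice patches.

The system is represented at two resolutions simultaneously, the way
integrative-modeling platforms do it: structured regions carry one bead per
residue (fine, used to measure crosslink distances at Calpha level) plus
up-to-``bead_max``-residue scoring beads (used for excluded volume and
connectivity); disordered regions carry scoring beads only. Structured regions
are rigid bodies: all their beads move together, so intra-body distances are
exact constants of the sampling.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .geometry import RigidTransform
from .residue_data import bead_mass, bead_radius

ENTITIES = {"alpha_tubulin", "beta_tubulin", "ndc", "cdc", "linker", "ctail", "other"}

# DCX construct boundaries (UniProt numbering, 1-based)
NDC_RANGE = (51, 140)
CDC_RANGE_GLOBULAR = (174, 251)
CDC_RANGE_OPEN = (174, 253)
UNMODELED_NTAIL = (1, 50)
UNMODELED_CTAIL = (331, 360)


@dataclass
class Residue:
    resnum: int
    aa: str
    ca_xyz: Optional[np.ndarray] = None


@dataclass
class Chain:
    chain_id: str
    entity: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        nums = [r.resnum for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"chain {self.chain_id}: resnums not strictly increasing")

    @property
    def resnums(self) -> list[int]:
        return [r.resnum for r in self.residues]

    def ca_array(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], float)

    def centroid(self) -> np.ndarray:
        xyz = [r.ca_xyz for r in self.residues if r.ca_xyz is not None]
        return np.mean(np.asarray(xyz, float), axis=0)


@dataclass
class ChainSet:
    chains: list[Chain]

    def get(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def by_entity(self, entity: str) -> list[Chain]:
        return [c for c in self.chains if c.entity == entity]

    def merged(self, other: "ChainSet") -> "ChainSet":
        ids = set(self.chain_ids) & set(other.chain_ids)
        if ids:
            raise ValueError(f"duplicate chain ids on merge: {sorted(ids)}")
        return ChainSet(self.chains + other.chains)


@dataclass
class Bead:
    id: int
    chain_id: str
    residue_range: tuple[int, int]
    center: np.ndarray
    radius: float
    mass: float
    in_rigid_body: Optional[int] = None
    resolution: int = 10  # 1 = fine (per residue), >1 = scoring bead

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("bead radius must be positive")
        if self.residue_range[1] < self.residue_range[0]:
            raise ValueError("empty residue range")


@dataclass
class RigidBody:
    id: int
    bead_ids: list[int]
    fixed: bool = False


@dataclass
class Topology:
    """Coarse-grained system: scoring beads, optional fine beads, rigid bodies.

    Bead ids index a single global coordinate array covering scoring beads
    first, then fine beads (``reference_coords`` row i is bead id i).
    """

    beads: list[Bead]
    fine_beads: list[Bead]
    rigid_bodies: list[RigidBody]
    bonded_pairs: list[tuple[int, int]]
    entity_of_chain: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._all = self.beads + self.fine_beads
        for i, b in enumerate(self._all):
            if b.id != i:
                raise ValueError("bead ids must index the global bead list")
        self._site_fine: dict[tuple[str, int], int] = {}
        self._site_coarse: dict[tuple[str, int], int] = {}
        for b in self.fine_beads:
            self._site_fine[(b.chain_id, b.residue_range[0])] = b.id
        for b in self.beads:
            for r in range(b.residue_range[0], b.residue_range[1] + 1):
                self._site_coarse[(b.chain_id, r)] = b.id
        self._rb_of = {bid: rb.id for rb in self.rigid_bodies for bid in rb.bead_ids}

    @property
    def all_beads(self) -> list[Bead]:
        return self._all

    @property
    def n_beads(self) -> int:
        return len(self._all)

    def reference_coords(self) -> np.ndarray:
        return np.array([b.center for b in self._all], float)

    @property
    def scoring_indices(self) -> np.ndarray:
        return np.array([b.id for b in self.beads], int)

    def rigid_body_of(self, bead_id: int) -> Optional[int]:
        return self._rb_of.get(bead_id)

    def site_bead(self, chain_id: str, resnum: int) -> int:
        """Bead carrying a residue: the fine (Calpha) bead where the region is
        structured, otherwise the containing scoring bead."""
        key = (chain_id, resnum)
        if key in self._site_fine:
            return self._site_fine[key]
        if key in self._site_coarse:
            return self._site_coarse[key]
        raise KeyError(f"residue {resnum} of chain {chain_id} is not modeled")

    def chains_of_entity(self, entity: str) -> list[str]:
        return [cid for cid, e in self.entity_of_chain.items() if e == entity]

    def mobile_rigid_bodies(self) -> list[RigidBody]:
        return [rb for rb in self.rigid_bodies if not rb.fixed]

    def free_bead_ids(self) -> list[int]:
        return [b.id for b in self.beads if b.in_rigid_body is None]

    def fixed_bead_ids(self) -> np.ndarray:
        fixed = []
        for rb in self.rigid_bodies:
            if rb.fixed:
                fixed.extend(rb.bead_ids)
        return np.array(sorted(fixed), int)

    def beads_of_chains(self, chain_ids: Iterable[str], scoring_only: bool = True) -> np.ndarray:
        cset = set(chain_ids)
        src = self.beads if scoring_only else self._all
        return np.array([b.id for b in src if b.chain_id in cset], int)

    def merged(self, other: "Topology") -> "Topology":
        """Concatenate two topologies into one global bead numbering."""
        import copy

        nb, onb = len(self.beads), len(other.beads)
        nf = len(self.fine_beads)
        # new layout: [self.scoring | other.scoring | self.fine | other.fine]
        remap_self = {b.id: i for i, b in enumerate(self.beads)}
        remap_self.update({b.id: nb + onb + i for i, b in enumerate(self.fine_beads)})
        remap_other = {b.id: nb + i for i, b in enumerate(other.beads)}
        remap_other.update({b.id: nb + onb + nf + i for i, b in enumerate(other.fine_beads)})
        rb_off = len(self.rigid_bodies)

        def clone(b: Bead, remap: dict[int, int], rboff: int) -> Bead:
            nb2 = copy.deepcopy(b)
            nb2.id = remap[b.id]
            if nb2.in_rigid_body is not None:
                nb2.in_rigid_body += rboff
            return nb2

        new_beads = [clone(b, remap_self, 0) for b in self.beads] + \
                    [clone(b, remap_other, rb_off) for b in other.beads]
        new_fine = [clone(b, remap_self, 0) for b in self.fine_beads] + \
                   [clone(b, remap_other, rb_off) for b in other.fine_beads]
        new_rbs = [RigidBody(i, [remap_self[b] for b in rb.bead_ids], rb.fixed)
                   for i, rb in enumerate(self.rigid_bodies)]
        new_rbs += [RigidBody(rb_off + i, [remap_other[b] for b in rb.bead_ids], rb.fixed)
                    for i, rb in enumerate(other.rigid_bodies)]
        new_bonds = [(remap_self[i], remap_self[j]) for i, j in self.bonded_pairs]
        new_bonds += [(remap_other[i], remap_other[j]) for i, j in other.bonded_pairs]
        ents = dict(self.entity_of_chain)
        ents.update(other.entity_of_chain)
        return Topology(new_beads, new_fine, new_rbs, new_bonds, ents)


# ---------------------------------------------------------------------------
# structure IO

def load_structure(path: str | Path, fmt: str = "pdb",
                   entity_map: Optional[dict[str, str]] = None) -> ChainSet:
    """Read a PDB/mmCIF file into a ChainSet of Calpha traces.

    ``entity_map`` assigns each chain id an entity label (alpha_tubulin, ndc,
    ...); unmapped chains get entity "other".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
    elif fmt == "mmcif":
        st = gemmi.read_structure(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    st.setup_entities()
    entity_map = entity_map or {}
    chains = []
    model = st[0]
    seen = set()
    for ch in model:
        residues = []
        for res in ch:
            ca = res.find_atom("CA", "*")
            info = gemmi.find_tabulated_residue(res.name)
            aa = info.one_letter_code.upper() if info else "X"
            if not aa.isalpha():
                continue
            xyz = np.array([ca.pos.x, ca.pos.y, ca.pos.z]) if ca else None
            residues.append(Residue(res.seqid.num, aa, xyz))
        if residues and ch.name not in seen:
            seen.add(ch.name)
            chains.append(Chain(ch.name, entity_map.get(ch.name, "other"), residues))
    if not chains or not any(r.ca_xyz is not None for c in chains for r in c.residues):
        raise ValueError(f"{path}: no chains with Calpha coordinates")
    missing = set(entity_map) - {c.chain_id for c in chains}
    if missing:
        raise ValueError(f"entity map references absent chains: {sorted(missing)}")
    return ChainSet(chains)


def write_pdb(chains: ChainSet, path: str | Path) -> None:
    """Write a Calpha-only multi-chain PDB."""
    st = gemmi.Structure()
    st.name = "dcxlattice"
    model = gemmi.Model("1")
    serial = 1
    for c in chains.chains:
        ch = gemmi.Chain(c.chain_id)
        for r in c.residues:
            if r.ca_xyz is None:
                continue
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE.get(r.aa, "GLY")
            res.seqid = gemmi.SeqId(r.resnum, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*r.ca_xyz)
            atom.serial = serial
            serial += 1
            res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# ---------------------------------------------------------------------------
# coarse-grained representation

def _chunks(n: int, k: int) -> list[int]:
    """Split n items into ceil(n/k) nearly equal chunks, each <= k."""
    m = -(-n // k)
    base, extra = divmod(n, m)
    return [base + (1 if i < extra else 0) for i in range(m)]


def build_representation(
    chains: ChainSet,
    structured_ranges: dict[str, list[tuple[int, int]]],
    bead_max: int = 10,
    exclude_ranges: Optional[dict[str, list[tuple[int, int]]]] = None,
    fixed_entities: Sequence[str] = (),
    fixed_ranges: Optional[dict[str, list[tuple[int, int]]]] = None,
    seed: int = 0,
) -> Topology:
    """Build the two-resolution bead representation.

    ``structured_ranges``/``exclude_ranges`` are keyed by entity and applied to
    every chain of that entity. Structured ranges become rigid bodies carrying
    both per-residue (fine) beads and <=bead_max-residue scoring beads;
    everything else becomes free scoring beads initialized on a jittered
    straight path bridging the flanking structured anchors.
    """
    rng = np.random.default_rng(seed)
    exclude_ranges = exclude_ranges or {}
    fixed_ranges = fixed_ranges or {}
    scoring: list[Bead] = []
    fine: list[Bead] = []
    rbs: list[RigidBody] = []
    bonds: list[tuple[int, int]] = []
    pending_fine: list[tuple[int, Residue, str, int]] = []  # (rb_idx, res, chain, seg)

    for chain in chains.chains:
        sranges = structured_ranges.get(chain.entity, [])
        xranges = exclude_ranges.get(chain.entity, [])
        for lo, hi in sranges:
            for lo2, hi2 in sranges:
                if (lo, hi) != (lo2, hi2) and lo <= hi2 and lo2 <= hi:
                    raise ValueError(f"overlapping structured ranges for {chain.entity}")

        def in_any(n: int, ranges) -> bool:
            return any(lo <= n <= hi for lo, hi in ranges)

        residues = [r for r in chain.residues if not in_any(r.resnum, xranges)]
        if not residues:
            continue
        # split into alternating structured / flexible segments
        segments: list[tuple[bool, list[Residue]]] = []
        for r in residues:
            s = in_any(r.resnum, sranges)
            if segments and segments[-1][0] == s:
                segments[-1][1].append(r)
            else:
                segments.append((s, [r]))

        chain_scoring: list[int] = []  # local indices into `scoring` for bonding
        flex_todo: list[tuple[list[int], list[Residue], Optional[int], Optional[int]]] = []

        for structured, seg in segments:
            if structured:
                if any(r.ca_xyz is None for r in seg):
                    missing = [r.resnum for r in seg if r.ca_xyz is None]
                    raise ValueError(
                        f"structured range of chain {chain.chain_id} lacks coordinates "
                        f"at residues {missing[:5]}"
                    )
                rb_idx = len(rbs)
                rb_beads: list[int] = []
                pos = 0
                for size in _chunks(len(seg), bead_max):
                    sub = seg[pos: pos + size]
                    pos += size
                    aas = "".join(r.aa for r in sub)
                    idx = len(scoring)
                    scoring.append(Bead(
                        id=idx, chain_id=chain.chain_id,
                        residue_range=(sub[0].resnum, sub[-1].resnum),
                        center=np.mean([r.ca_xyz for r in sub], axis=0),
                        radius=bead_radius(aas), mass=bead_mass(aas),
                        in_rigid_body=rb_idx, resolution=bead_max,
                    ))
                    rb_beads.append(idx)
                    chain_scoring.append(idx)
                for r in seg:
                    pending_fine.append((rb_idx, r, chain.chain_id, 0))
                seg_lo, seg_hi = seg[0].resnum, seg[-1].resnum
                fixed = chain.entity in set(fixed_entities) or any(
                    lo <= seg_lo and seg_hi <= hi
                    for lo, hi in fixed_ranges.get(chain.entity, []))
                rbs.append(RigidBody(rb_idx, rb_beads, fixed=fixed))
            else:
                anchor_prev = chain_scoring[-1] if chain_scoring else None
                placeholder: list[int] = []
                pos = 0
                for size in _chunks(len(seg), bead_max):
                    sub = seg[pos: pos + size]
                    pos += size
                    aas = "".join(r.aa for r in sub)
                    idx = len(scoring)
                    scoring.append(Bead(
                        id=idx, chain_id=chain.chain_id,
                        residue_range=(sub[0].resnum, sub[-1].resnum),
                        center=np.zeros(3),  # placed after anchors are known
                        radius=bead_radius(aas), mass=bead_mass(aas),
                        in_rigid_body=None, resolution=bead_max,
                    ))
                    placeholder.append(idx)
                    chain_scoring.append(idx)
                flex_todo.append((placeholder, seg, anchor_prev, None))

        # fill in the trailing anchors of flexible segments
        for item in flex_todo:
            idxs, seg, aprev, _ = item
            last = idxs[-1]
            after = [i for i in chain_scoring if i > last and scoring[i].in_rigid_body is not None]
            anext = min(after) if after else None
            _place_flexible(scoring, idxs, aprev, anext, rng)

        for a, b in zip(chain_scoring, chain_scoring[1:]):
            bonds.append((a, b))

    # fine beads come after all scoring beads in the global id space
    n_s = len(scoring)
    for k, (rb_idx, r, cid, _) in enumerate(pending_fine):
        bead = Bead(
            id=n_s + k, chain_id=cid, residue_range=(r.resnum, r.resnum),
            center=np.array(r.ca_xyz, float), radius=bead_radius(r.aa),
            mass=bead_mass(r.aa), in_rigid_body=rb_idx, resolution=1,
        )
        fine.append(bead)
        rbs[rb_idx].bead_ids.append(bead.id)

    ents = {c.chain_id: c.entity for c in chains.chains}
    return Topology(scoring, fine, rbs, bonds, ents)


def _place_flexible(scoring: list[Bead], idxs: list[int],
                    anchor_prev: Optional[int], anchor_next: Optional[int],
                    rng: np.random.Generator) -> None:
    """Initial positions: straight path between anchors, jitter <= 1 A."""
    n = len(idxs)
    if anchor_prev is not None and anchor_next is not None:
        a = scoring[anchor_prev].center
        b = scoring[anchor_next].center
        ts = np.linspace(0, 1, n + 2)[1:-1]
        pts = a[None, :] + ts[:, None] * (b - a)[None, :]
    else:
        anchor = anchor_prev if anchor_prev is not None else anchor_next
        a = scoring[anchor].center if anchor is not None else np.zeros(3)
        step = 2.0 * np.mean([scoring[i].radius for i in idxs])
        direction = np.array([1.0, 0.0, 0.0])
        offs = np.arange(1, n + 1)[:, None] * step * direction[None, :]
        pts = a[None, :] + (offs if anchor_prev is not None or anchor is None else -offs[::-1])
    pts = pts + rng.uniform(-1.0, 1.0, size=(n, 3)) * (1.0 / np.sqrt(3.0))
    for i, p in zip(idxs, pts):
        scoring[i].center = p


# ---------------------------------------------------------------------------
# lattice patch

@dataclass
class Junction:
    """A lattice vertex; interior junctions are flanked by four complete dimers."""
    id: tuple[int, int]  # (protofilament slot, dimer slot) of the lower-left dimer
    position: np.ndarray
    interior: bool
    flanking_dimers: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class LatticePatch:
    monomers: list[tuple[str, str, int, int]]  # (chain_id, kind, pf_index, long_index)
    lateral_T: RigidTransform
    longitudinal_T: RigidTransform
    n_protofilaments: int
    n_dimers: int
    junctions: list[Junction]

    @property
    def interior_junctions(self) -> list[Junction]:
        return [j for j in self.junctions if j.interior]

    def junction_by_id(self, jid: tuple[int, int]) -> Junction:
        for j in self.junctions:
            if j.id == tuple(jid):
                return j
        raise KeyError(jid)

    def nearest_junction(self, point: np.ndarray) -> Junction:
        """Nearest vertex; ties broken toward interior junctions."""
        point = np.asarray(point, float)
        ds = np.array([np.linalg.norm(j.position - point) for j in self.junctions])
        best = ds.min()
        cands = [j for j, d in zip(self.junctions, ds) if d <= best + 1e-9]
        cands.sort(key=lambda j: (not j.interior,))
        return cands[0]


_CHAIN_POOL = string.ascii_uppercase + string.ascii_lowercase + string.digits


def build_lattice_patch(
    dimer: ChainSet,
    n_protofilaments: int,
    n_dimers: int,
    lateral_T: RigidTransform,
    longitudinal_T: RigidTransform,
    min_spacing: float = 15.0,
) -> tuple[ChainSet, LatticePatch]:
    """Replicate an alpha/beta dimer into an n_protofilaments x n_dimers patch.

    The patch is planar: only the local junction geometry matters for domain
    docking, so full helical lattice parameters are not needed. Chain ids are
    uniquified; interior junctions (four complete flanking dimers) are
    enumerated on the (protofilament, dimer) grid.
    """
    if not (lateral_T.is_proper and longitudinal_T.is_proper):
        raise ValueError("lattice transforms must be proper rigid transforms")
    chains: list[Chain] = []
    monomers: list[tuple[str, str, int, int]] = []
    dimer_centroids: dict[tuple[int, int], list[np.ndarray]] = {}
    pool = iter(_CHAIN_POOL)
    for p in range(n_protofilaments):
        lat = lateral_T.power(p)
        for d in range(n_dimers):
            T = lat.compose(longitudinal_T.power(d))
            for sub, src in enumerate(dimer.chains):
                kind = "alpha" if src.entity == "alpha_tubulin" else "beta"
                try:
                    cid = next(pool)
                except StopIteration as e:
                    raise ValueError("patch too large for unique 1-char chain ids") from e
                residues = [
                    Residue(r.resnum, r.aa,
                            T.apply(r.ca_xyz) if r.ca_xyz is not None else None)
                    for r in src.residues
                ]
                chains.append(Chain(cid, src.entity, residues))
                monomers.append((cid, kind, p, 2 * d + sub))
                dimer_centroids.setdefault((p, d), []).append(chains[-1].centroid())

    # steric sanity: monomer centroids must stay apart
    cents = np.array([c.centroid() for c in chains])
    if len(cents) > 1:
        dmat = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=-1)
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() < min_spacing:
            raise ValueError(
                f"lattice transforms produce steric collapse "
                f"(min centroid spacing {dmat.min():.1f} A < {min_spacing} A)"
            )

    dim_cent = {k: np.mean(v, axis=0) for k, v in dimer_centroids.items()}
    a_vec = _lattice_vector(dim_cent, axis=0, n1=n_protofilaments, n2=n_dimers)
    b_vec = _lattice_vector(dim_cent, axis=1, n1=n_protofilaments, n2=n_dimers)
    origin = dim_cent[(0, 0)]
    junctions = []
    for p in range(-1, n_protofilaments):
        for d in range(-1, n_dimers):
            interior = 0 <= p <= n_protofilaments - 2 and 0 <= d <= n_dimers - 2
            if interior:
                pos = np.mean([dim_cent[(p, d)], dim_cent[(p + 1, d)],
                               dim_cent[(p, d + 1)], dim_cent[(p + 1, d + 1)]], axis=0)
                flank = [(p, d), (p + 1, d), (p, d + 1), (p + 1, d + 1)]
            else:
                pos = origin + (p + 0.5) * a_vec + (d + 0.5) * b_vec
                flank = []
            junctions.append(Junction((p, d), pos, interior, flank))
    patch = LatticePatch(monomers, lateral_T, longitudinal_T,
                         n_protofilaments, n_dimers, junctions)
    return ChainSet(chains), patch


def _lattice_vector(dim_cent, axis: int, n1: int, n2: int) -> np.ndarray:
    diffs = []
    for (p, d), c in dim_cent.items():
        nb = (p + 1, d) if axis == 0 else (p, d + 1)
        if nb in dim_cent:
            diffs.append(dim_cent[nb] - c)
    if not diffs:  # single row/column: fall back to the transform translation
        return np.zeros(3)
    return np.mean(diffs, axis=0)


def minimal_repeat(patch: LatticePatch, junction_id: tuple[int, int] = (0, 0)) -> list[str]:
    """Chain ids of the minimal repeat unit around a junction: 2 alpha + 4 beta
    monomers containing every B-lattice lateral and longitudinal contact."""
    p, d = junction_id
    j = patch.junction_by_id((p, d))
    if not j.interior:
        raise ValueError("minimal repeat requires an interior junction")
    wanted = set()
    for pf in (p, p + 1):
        wanted.add((pf, 2 * d + 1))      # beta of dimer d
        wanted.add((pf, 2 * (d + 1)))    # alpha of dimer d+1
        wanted.add((pf, 2 * (d + 1) + 1))  # beta of dimer d+1
    return [cid for cid, kind, pf, li in patch.monomers if (pf, li) in wanted]
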