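"""End-to-end orchestration of the four modeling stages.

Stage 1 docks a single DC domain onto the lattice (crosslinks only, or
crosslinks plus the EM density term) to identify the primary binding site.
Stages 2-3 fix two anchor domains at adjacent junctional sites (lateral,
longitudinal, or one of two diagonal geometries) and sample the dimerization
of the mobile C-terminal domains, in the globular or the open (domain-swapped)
form, against domain-domain crosslinks with copy ambiguity. Stage 4 adds the
domain-lattice crosslinks to orient the dimer.

The stage structure is data (StageSpec), not code paths, so restraint subsets
compose freely.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from .ensemble_analysis import (Cluster, cluster_models, crosslink_satisfaction,
                                filter_models, pairwise_rmsd, sampling_precision,
                                localization_density)
from .geometry import RigidTransform, random_rotation_uniform
from .restraints import (CrosslinkSet, GMM, RestraintParams, ScoringSystem,
                         fit_map_gmm)
from .sampling import Ensemble, MoveSet, SamplerConfig, run_replica_exchange
from .synthetic_data import (GroundTruth, make_toy_domain, make_toy_lattice,
                             place_chain, simulate_crosslinks, simulate_density)
from .topology import (Chain, ChainSet, LatticePatch, Residue, Topology,
                       build_representation)

RESTRAINT_SUBSETS = ("xl_only", "xl_plus_em", "dcx_dcx_only", "all")
GEOMETRIES = ("lateral", "longitudinal", "diagonal1", "diagonal2")
DEFAULT_THRESHOLD_GRID = (2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 45.0)


@dataclass
class StageSpec:
    stage: int
    restraint_subset: str = "xl_only"
    cdc_form: str = "globular"
    anchor_geometry: Optional[str] = None
    mobile: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3, 4):
            raise ValueError("stage must be 1-4")
        if self.restraint_subset not in RESTRAINT_SUBSETS:
            raise ValueError(f"unknown restraint subset {self.restraint_subset!r}")
        if self.stage == 1:
            if not self.mobile:
                self.mobile = ("ndc",)
            if len(self.mobile) != 1:
                raise ValueError("stage 1 has exactly one mobile domain")
        else:
            if self.anchor_geometry is None:
                raise ValueError("stages 2-4 need an anchor geometry")
            if self.anchor_geometry not in GEOMETRIES:
                raise ValueError(f"unknown geometry {self.anchor_geometry!r}")
        if self.cdc_form not in ("globular", "open"):
            raise ValueError("cdc_form must be 'globular' or 'open'")


@dataclass
class StageInputs:
    topology: Topology
    patch: LatticePatch
    xls: CrosslinkSet
    system: ScoringSystem
    mobile_selection: np.ndarray          # scoring beads used for RMSD/cluster/filter
    truth_coords: np.ndarray              # reference coordinates = ground-truth pose
    ground_truth: GroundTruth
    init_fn: Callable[[np.random.Generator], np.ndarray]
    data_gmm: Optional[GMM] = None


@dataclass
class EnsembleReport:
    spec: StageSpec
    n_sampled: int
    n_filtered: int
    sampling_precision_A: float
    precision_table: pd.DataFrame
    clusters: list[Cluster]
    cluster_table: pd.DataFrame
    satisfaction_table: pd.DataFrame
    unfiltered_top_precision_A: float
    artifacts: dict[str, str] = field(default_factory=dict)

    @property
    def top_cluster(self) -> Cluster:
        return self.clusters[0]

    @property
    def top_population(self) -> float:
        return self.top_cluster.population

    @property
    def top_precision_A(self) -> float:
        return self.top_cluster.precision

    @property
    def top_satisfaction(self) -> float:
        return float(self.cluster_table["satisfaction"].iloc[0])

    @property
    def top_rmsd_to_truth_A(self) -> float:
        return float(self.cluster_table["centroid_rmsd_to_truth_A"].iloc[0])

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cluster_table.to_csv(directory / "clusters.csv", index=False)
        self.precision_table.to_csv(directory / "sampling_precision.csv", index=False)
        self.satisfaction_table.to_csv(directory / "satisfaction.csv", index=False)
        summary = {
            "stage": self.spec.stage,
            "restraint_subset": self.spec.restraint_subset,
            "cdc_form": self.spec.cdc_form,
            "anchor_geometry": self.spec.anchor_geometry,
            "n_sampled": int(self.n_sampled),
            "n_filtered": int(self.n_filtered),
            "sampling_precision_A": float(self.sampling_precision_A),
            "unfiltered_top_precision_A": float(self.unfiltered_top_precision_A),
            "top_cluster": {
                "population": float(self.top_population),
                "precision_A": float(self.top_precision_A),
                "satisfaction": float(self.top_satisfaction),
                "centroid_rmsd_to_truth_A": float(self.top_rmsd_to_truth_A),
            },
            "artifacts": dict(self.artifacts),
        }
        with open(directory / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=False)
        self.artifacts["summary"] = str(directory / "summary.yaml")


# ---------------------------------------------------------------------------
# synthetic stage builders

_Z_GAP = 1.0  # required clearance between bead surfaces at the true pose


def _clearance_z(base_centers: np.ndarray, radii: np.ndarray,
                 mt_centers: np.ndarray, mt_radii: np.ndarray,
                 z_start: float = 10.0) -> float:
    """Smallest z-offset at which no scoring bead overlaps the lattice."""
    for z in np.arange(z_start, z_start + 60.0, 0.5):
        c = base_centers + np.array([0.0, 0.0, z])
        d = np.linalg.norm(c[:, None, :] - mt_centers[None, :, :], axis=-1)
        if np.min(d - (radii[:, None] + mt_radii[None, :])) >= _Z_GAP:
            return float(z)
    raise RuntimeError("no clearance found above the lattice")


def _chunk_centers(chain: Chain, bead_max: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Scoring-bead centers/radii a chain would get, without building topology."""
    from .residue_data import bead_radius
    from .topology import _chunks

    xyz = chain.ca_array()
    aas = "".join(r.aa for r in chain.residues)
    centers, radii = [], []
    pos = 0
    for size in _chunks(len(xyz), bead_max):
        centers.append(xyz[pos:pos + size].mean(axis=0))
        radii.append(bead_radius(aas[pos:pos + size]))
        pos += size
    return np.array(centers), np.array(radii)


def _patch_box(patch: LatticePatch, margin: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([j.position for j in patch.interior_junctions])
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    return lo, hi


def build_stage1_inputs(spec: StageSpec, seed: int = 0, n_true: int = 30,
                        decoy_fraction: float = 0.0,
                        n_protofilaments: int = 3, n_dimers: int = 3,
                        domain_n_residues: int = 30,
                        params: Optional[RestraintParams] = None,
                        junction: tuple[int, int] = (0, 0),
                        em_noise_sd: float = 0.0) -> StageInputs:
    """Monomeric domain docking scenario with known ground truth."""
    rng = np.random.default_rng(seed)
    params = params or RestraintParams()
    chains_mt, patch = make_toy_lattice(n_protofilaments, n_dimers, seed=seed)
    entity = spec.mobile[0]
    domain = make_toy_domain(domain_n_residues, seed + 1, chain_id="X", entity=entity)
    R = random_rotation_uniform(rng)

    # ground-truth pose: docked over the target junction at minimal clearance
    jpos = patch.junction_by_id(junction).position
    c0, r0 = _chunk_centers(domain)
    mt_centers, mt_radii = [], []
    for ch in chains_mt.chains:
        c, r = _chunk_centers(ch)
        mt_centers.append(c)
        mt_radii.append(r)
    mt_centers = np.concatenate(mt_centers)
    mt_radii = np.concatenate(mt_radii)
    base = (c0 @ R.T) + jpos
    z = _clearance_z(base, r0, mt_centers, mt_radii)
    pose = RigidTransform(R, jpos + np.array([0.0, 0.0, z]))
    placed = place_chain(domain, pose)

    combined = chains_mt.merged(ChainSet([placed]))
    n_mono = len(chains_mt.chains[0].residues)
    topology = build_representation(
        combined,
        structured_ranges={"alpha_tubulin": [(1, n_mono)], "beta_tubulin": [(1, n_mono)],
                           entity: [(1, domain_n_residues)]},
        fixed_entities=("alpha_tubulin", "beta_tubulin"), seed=seed,
    )
    xls, gt = simulate_crosslinks(ChainSet([placed]), chains_mt, n_true,
                                  decoy_fraction=decoy_fraction, seed=seed + 2,
                                  copy_specific=(False, True))
    gt.poses[entity] = pose
    gt.true_junction = junction

    mobile_sel = topology.beads_of_chains(["X"])
    data_gmm = None
    if spec.restraint_subset == "xl_plus_em":
        beads = [topology.all_beads[i] for i in mobile_sel]
        dm = simulate_density(np.array([b.center for b in beads]),
                              np.array([b.radius for b in beads]),
                              np.array([b.mass for b in beads]),
                              resolution=8.0, noise_sd=em_noise_sd, seed=seed + 3)
        data_gmm = fit_map_gmm(dm, n_components=min(3, len(beads)), seed=seed + 4)
    system = ScoringSystem(topology, xls, params, data_gmm=data_gmm,
                           em_selection=mobile_sel if data_gmm is not None else None)
    init_fn = _make_init_fn(topology, patch)
    return StageInputs(topology, patch, xls, system, mobile_sel,
                       topology.reference_coords(), gt, init_fn, data_gmm)


def anchor_junctions(patch: LatticePatch, geometry: str) -> tuple:
    """The two interior junctions anchoring the dimer for a given geometry."""
    pairs = {
        "lateral": ((0, 0), (1, 0)),
        "longitudinal": ((0, 0), (0, 1)),
        "diagonal1": ((0, 0), (1, 1)),
        "diagonal2": ((1, 0), (0, 1)),
    }[geometry]
    out = []
    for jid in pairs:
        try:
            j = patch.junction_by_id(jid)
        except KeyError:
            j = None
        if j is None or not j.interior:
            raise ValueError(
                f"{geometry} anchors need two interior junctions; patch of "
                f"{patch.n_protofilaments}x{patch.n_dimers} dimers lacks them")
        out.append(j)
    return tuple(out)


def _cdc_blob(form: str, seed: int) -> Chain:
    elong = 2.2 if form == "open" else 1.0
    radius = 8.0 if form == "open" else None
    return make_toy_domain(24, seed, entity="dcx", elongation=elong, radius=radius)


def build_dimer_inputs(spec: StageSpec, seed: int = 0, n_true_dcx: int = 20,
                       n_true_mt: int = 10, decoy_fraction: float = 0.0,
                       n_protofilaments: int = 3, n_dimers: int = 3,
                       truth_form: Optional[str] = None,
                       params: Optional[RestraintParams] = None) -> StageInputs:
    """Two-copy scenario: anchor domains fixed at adjacent junctions, mobile
    C-terminal domains + flexible linker/tail, with copy-ambiguous crosslinks.

    ``truth_form`` sets the CDC conformation the synthetic data are generated
    from (default: same as the modeled ``spec.cdc_form``); modeling one form
    against the other's data is how the form preference is assessed.
    """
    params = params or RestraintParams()
    truth_form = truth_form or spec.cdc_form
    chains_mt, patch = make_toy_lattice(n_protofilaments, n_dimers, seed=seed)
    ja, jb = anchor_junctions(patch, spec.anchor_geometry)

    anchor = make_toy_domain(24, seed + 11, entity="dcx")
    cdc = _cdc_blob(truth_form, seed + 12)
    cdc_model = cdc if truth_form == spec.cdc_form else _cdc_blob(spec.cdc_form, seed + 12)

    mt_centers, mt_radii = [], []
    for ch in chains_mt.chains:
        c, r = _chunk_centers(ch)
        mt_centers.append(c)
        mt_radii.append(r)
    mt_centers = np.concatenate(mt_centers)
    mt_radii = np.concatenate(mt_radii)

    a_c, a_r = _chunk_centers(anchor)
    z_anchor = _clearance_z(a_c + ja.position, a_r, mt_centers, mt_radii)
    c_c, c_r = _chunk_centers(cdc)
    cm_c, cm_r = _chunk_centers(cdc_model)
    mid = 0.5 * (ja.position + jb.position)
    axis = jb.position - ja.position
    axis = axis / np.linalg.norm(axis)
    sep = 0.95 * float(np.max(np.linalg.norm(cdc.ca_array(), axis=1)))
    z_cdc = _clearance_z(np.concatenate([c_c - sep * axis + mid,
                                         c_c + sep * axis + mid,
                                         cm_c - sep * axis + mid,
                                         cm_c + sep * axis + mid]),
                         np.concatenate([c_r, c_r, cm_r, cm_r]),
                         mt_centers, mt_radii, z_start=z_anchor)

    def build_copies(cdc_blob: Chain) -> list[Chain]:
        out = []
        for cid, jpos, sign in (("1", ja.position, -1.0), ("2", jb.position, +1.0)):
            rot = np.eye(3) if sign < 0 else _rot_z_pi()  # head-to-tail dimer
            anchor_pose = RigidTransform(np.eye(3), jpos + np.array([0, 0, z_anchor]))
            cdc_pose = RigidTransform(
                rot, mid + sign * sep * axis + np.array([0, 0, z_cdc]))
            residues = []
            for r in anchor.residues:
                residues.append(Residue(r.resnum, r.aa, anchor_pose.apply(r.ca_xyz)))
            a_end = residues[-1].ca_xyz
            cdc_start = cdc_pose.apply(cdc_blob.residues[0].ca_xyz)
            for k, rn in enumerate(range(25, 37)):  # linker, 12 residues
                t = (k + 1) / 13.0
                residues.append(Residue(rn, "G", a_end + t * (cdc_start - a_end)))
            for r in cdc_blob.residues:
                residues.append(Residue(r.resnum + 36, r.aa, cdc_pose.apply(r.ca_xyz)))
            c_end = residues[-1].ca_xyz
            for k, rn in enumerate(range(61, 69)):  # C-tail, away from the lattice
                residues.append(Residue(rn, "S", c_end + np.array([0, 0, 4.0 * (k + 1)])))
            out.append(Chain(cid, "dcx", residues))
        return out

    copies = build_copies(cdc)                     # ground-truth coordinates
    model_copies = (copies if cdc_model is cdc
                    else build_copies(cdc_model))  # modeled representation

    combined = chains_mt.merged(ChainSet(model_copies))
    n_mono = len(chains_mt.chains[0].residues)
    topology = build_representation(
        combined,
        structured_ranges={"alpha_tubulin": [(1, n_mono)], "beta_tubulin": [(1, n_mono)],
                           "dcx": [(1, 24), (37, 60)]},
        fixed_entities=("alpha_tubulin", "beta_tubulin"),
        fixed_ranges={"dcx": [(1, 24)]},  # anchors are fixed, CDCs sample
        seed=seed,
    )
    xls, gt = simulate_crosslinks(ChainSet([copies[0]]), ChainSet([copies[1]]),
                                  n_true_dcx, decoy_fraction=decoy_fraction,
                                  seed=seed + 2, restrict1=(37, 68),
                                  restrict2=(37, 68), inter_copy_only=True,
                                  id_prefix="dd")
    if spec.restraint_subset == "all" and spec.stage == 4:
        xls_mt, _ = simulate_crosslinks(ChainSet(copies), chains_mt, n_true_mt,
                                        seed=seed + 3, restrict1=(25, 68),
                                        copy_specific=(False, True), id_prefix="dm")
        xls = CrosslinkSet(xls.links + xls_mt.links)
    gt.true_junction = ja.id
    gt.poses["cdc_1"] = RigidTransform(np.eye(3), mid - sep * axis + [0, 0, z_cdc])
    gt.poses["cdc_2"] = RigidTransform(np.eye(3), mid + sep * axis + [0, 0, z_cdc])

    mobile_sel = np.array([
        b.id for b in topology.beads
        if b.chain_id in ("1", "2") and 37 <= b.residue_range[0] <= 60
    ])
    system = ScoringSystem(topology, xls, params)
    init_fn = _make_init_fn(topology, patch)
    return StageInputs(topology, patch, xls, system, mobile_sel,
                       topology.reference_coords(), gt, init_fn)


def _rot_z_pi() -> np.ndarray:
    return np.diag([-1.0, -1.0, 1.0])


def _make_init_fn(topology: Topology, patch: LatticePatch,
                  z_range: tuple[float, float] = (12.0, 45.0)):
    """Randomize mobile rigid bodies uniformly over the patch interior and
    collapse free beads near their chain's placed beads; fixed parts untouched."""
    lo, hi = _patch_box(patch)
    ref = topology.reference_coords()
    mobile_rbs = [np.asarray(rb.bead_ids, int) for rb in topology.mobile_rigid_bodies()]
    free = topology.free_bead_ids()
    chain_of = {b.id: b.chain_id for b in topology.all_beads}

    def init(rng: np.random.Generator) -> np.ndarray:
        coords = ref.copy()
        for idx in mobile_rbs:
            sub = ref[idx]
            centroid = sub.mean(axis=0)
            R = random_rotation_uniform(rng)
            target = np.array([rng.uniform(lo[0], hi[0]), rng.uniform(lo[1], hi[1]),
                               rng.uniform(*z_range)])
            coords[idx] = (sub - centroid) @ R.T + target
        for bid in free:
            cid = chain_of[bid]
            placed = [i for rb in topology.rigid_bodies for i in rb.bead_ids
                      if chain_of[i] == cid]
            base = coords[placed].mean(axis=0) if placed else 0.5 * (lo + hi)
            coords[bid] = base + rng.normal(0.0, 3.0, size=3)
        return coords

    return init


def build_stage_inputs(spec: StageSpec, seed: int = 0, **kwargs) -> StageInputs:
    if spec.stage == 1:
        return build_stage1_inputs(spec, seed=seed, **kwargs)
    return build_dimer_inputs(spec, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# stage runner

def run_stage(spec: StageSpec, inputs: StageInputs, sampler_config: SamplerConfig,
              moveset: Optional[MoveSet] = None,
              threshold_grid=DEFAULT_THRESHOLD_GRID,
              score_quantile: float = 0.5,
              write_dir: Optional[str | Path] = None,
              write_density: bool = False) -> EnsembleReport:
    """Sample, filter, cluster, and validate one modeling stage."""
    if spec.restraint_subset == "xl_plus_em" and inputs.data_gmm is None:
        raise ValueError("xl_plus_em requires an EM density (data_gmm missing)")
    ensemble = run_replica_exchange(inputs.system, sampler_config,
                                    moveset=moveset, init_fn=inputs.init_fn)
    filtered, _ = filter_models(ensemble, inputs.patch, inputs.mobile_selection,
                                score_quantile=score_quantile)
    if len(filtered) < 4:
        raise RuntimeError("too few models survive filtering; increase sampling")
    stack = filtered.coords_stack()
    scores = filtered.scores
    sel = inputs.mobile_selection

    if len(np.unique(filtered.run_labels)) >= 2:
        sp, sp_table = sampling_precision(stack, scores, filtered.run_labels,
                                          threshold_grid, selection=sel)
    else:  # a whole run was filtered out: precision is not measurable
        sp, sp_table = float("inf"), pd.DataFrame(
            columns=["threshold", "n_clusters", "p_value", "cramers_v",
                     "frac_in_shared_clusters", "passed"])
    thr = sp if np.isfinite(sp) else float(max(threshold_grid))
    clusters = cluster_models(stack, scores, thr, selection=sel)
    sat = crosslink_satisfaction(filtered, inputs.xls, inputs.topology, clusters)

    # pre-filter (whole-ensemble) top-cluster precision, for comparison
    full_clusters = cluster_models(ensemble.coords_stack(), ensemble.scores,
                                   thr, selection=sel)
    unfiltered_prec = full_clusters[0].precision

    rows = []
    for k, c in enumerate(clusters):
        rmsd_truth = pairwise_rmsd(stack[c.centroid], inputs.truth_coords, sel)
        rows.append({"cluster": k, "n_members": len(c.members),
                     "population": c.population, "precision_A": c.precision,
                     "satisfaction": sat.per_cluster[k],
                     "centroid_rmsd_to_truth_A": rmsd_truth})
    report = EnsembleReport(
        spec=spec, n_sampled=len(ensemble), n_filtered=len(filtered),
        sampling_precision_A=float(sp), precision_table=sp_table,
        clusters=clusters, cluster_table=pd.DataFrame(rows),
        satisfaction_table=sat.table(), unfiltered_top_precision_A=unfiltered_prec,
    )
    if write_dir is not None:
        write_dir = Path(write_dir)
        report.write(write_dir)
        ensemble.save(write_dir / "trajectory")
        report.artifacts["trajectory"] = str(write_dir / "trajectory")
        if write_density and clusters:
            beads = [inputs.topology.all_beads[i] for i in sel]
            dm = localization_density(
                filtered, clusters[0].members, sel,
                np.array([b.radius for b in beads]),
                np.array([b.mass for b in beads]))
            dm.write_mrc(write_dir / "top_cluster_density.mrc")
            report.artifacts["density"] = str(write_dir / "top_cluster_density.mrc")
    return report


def compare_reports(reports: dict[str, EnsembleReport],
                    margin: float = 0.05) -> tuple[pd.DataFrame, str]:
    """Rank modeling scenarios by top-cluster crosslink satisfaction.

    No winner is declared when the best and second-best satisfaction differ by
    less than ``margin``.
    """
    rows = []
    for name, rep in reports.items():
        rows.append({"scenario": name, "cdc_form": rep.spec.cdc_form,
                     "geometry": rep.spec.anchor_geometry,
                     "satisfaction": rep.top_satisfaction,
                     "precision_A": rep.top_precision_A,
                     "population": rep.top_population})
    df = pd.DataFrame(rows).sort_values(
        ["satisfaction", "precision_A"], ascending=[False, True]).reset_index(drop=True)
    if len(df) < 2 or df["satisfaction"].iloc[0] - df["satisfaction"].iloc[1] <= margin:
        verdict = "indistinguishable"
    else:
        verdict = str(df["scenario"].iloc[0])
    return df, verdict
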