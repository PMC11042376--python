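"""Coarse-grained 3D chromatid models built from 1D loop arrays.

A mitotic chromatid is modeled as a bottlebrush: consecutive chromatin loops
whose bases (condensin positions) lie on a backbone path, with the loop
interiors filling the space around it. Three backbone geometries are
provided:

* ``build_bottlebrush`` — backbone confined near the axis of a cylinder whose
  radius and length follow from the linear density (Mb/um along the axis)
  and volume density (Mb/um^3);
* ``apply_helical_scaffold`` — the same cylinder, but the backbone is nudged
  to follow an irregular helix with a fixed number of turns (condensin II
  chromatids); adjacent gyres then touch, which produces the periodic
  second/third diagonal bands in contact maps;
* ``build_periodic_random_walk`` — no cylinder: the backbone is a weakly
  stretched random walk with an imposed end-to-end distance (condensin I
  chromatids), giving contact scaling P(s) ~ s^-1.5 at multi-Mb range.

Construction is direct (anchored random walks plus Gaussian bridges for loop
interiors, with confinement and a local density cap) rather than Brownian
dynamics; thermal averaging is approximated by averaging over replicate
seeds. Geometry is in nm, genomic coordinates in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ChromatidParams",
    "Conformation",
    "CohesiveLinkSet",
    "build_bottlebrush",
    "apply_helical_scaffold",
    "build_periodic_random_walk",
    "build_chromatid",
    "build_sister_pair",
    "cross_section_profile",
    "realized_volume_density",
    "segments_from_loops",
]

CONDENSIN_II_BEST_FIT = dict(loop_bp=400_000, gap_nm=80.0, turn_mb=17.0,
                             linear_density_mb_um=42.5, volume_density_mb_um3=44.0,
                             helix_mode="helical_cylinder")
CONDENSIN_I_BEST_FIT = dict(loop_bp=100_000, gap_nm=20.0,
                            volume_density_mb_um3=77.0, end_to_end_um=4.0,
                            helix_mode="periodic_random_walk")


@dataclass
class ChromatidParams:
    """Free and fixed parameters of the chromatid model.

    ``loop_bp``, ``gap_nm`` and ``linear_density_mb_um`` are the free
    parameters fitted against P(s); ``turn_mb`` (genomic content of one
    helical turn, read from the second diagonal of Hi-C maps) and
    ``volume_density_mb_um3`` (from electron microscopy) are fixed inputs.
    The remaining fields are construction constants, documented in the
    methods note and deliberately coarse.
    """

    loop_bp: float = 400_000.0
    gap_nm: float = 80.0
    linear_density_mb_um: float = 42.5
    turn_mb: float | None = 17.0
    volume_density_mb_um3: float = 44.0
    helix_mode: str = "helical_cylinder"
    end_to_end_um: float = 4.0          # periodic_random_walk mode only
    bead_bp: int = 10_000
    # construction constants
    scaffold_radius_fraction: float = 0.45
    guide_pull: float = 0.6
    loop_width_factor: float = 2.0
    helix_z_jitter_nm: float = 60.0
    helix_phase_jitter_rad: float = 0.2
    jitter_corr_mb: float = 3.0
    backbone_persistence_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("loop_bp", "gap_nm", "linear_density_mb_um",
                     "volume_density_mb_um3", "bead_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 10 <= self.volume_density_mb_um3 <= 200:
            raise ValueError("volume density outside the plausible 10-200 Mb/um^3 band")
        if self.helix_mode not in ("helical_cylinder", "periodic_random_walk"):
            raise ValueError(f"unknown helix_mode {self.helix_mode!r}")

    # ---- derived geometry -------------------------------------------------
    def axis_length_nm(self, genome_bp: float) -> float:
        return genome_bp / 1e6 / self.linear_density_mb_um * 1000.0

    def cylinder_radius_nm(self, genome_bp: float) -> float:
        L_um = self.axis_length_nm(genome_bp) / 1000.0
        mb = genome_bp / 1e6
        return np.sqrt(mb / (self.volume_density_mb_um3 * np.pi * L_um)) * 1000.0

    @property
    def pitch_nm(self) -> float:
        """Axial rise of one helical turn: turn length / linear density."""
        if self.turn_mb is None:
            return np.inf
        return self.turn_mb / self.linear_density_mb_um * 1000.0

    @property
    def bead_diameter_nm(self) -> float:
        v_um3 = (self.bead_bp / 1e6) / self.volume_density_mb_um3
        return (6.0 * v_um3 / np.pi) ** (1.0 / 3.0) * 1000.0

    @property
    def brush_radius_nm(self) -> float:
        """Bottlebrush cross-section radius from volume-density closure."""
        lin = (self.loop_bp / 1e6) / (self.gap_nm / 1000.0)  # Mb per um backbone
        return np.sqrt(lin / (self.volume_density_mb_um3 * np.pi)) * 1000.0

    def winding_number(self, genome_bp: float) -> float:
        if self.turn_mb is None or not np.isfinite(self.turn_mb):
            return 0.0
        return genome_bp / 1e6 / self.turn_mb


@dataclass
class Conformation:
    """Bead path of one or two chromatids."""

    genomic_bp: np.ndarray            # per bead, strictly increasing per chromatid
    xyz: np.ndarray                   # (n, 3) nm
    bead_bp: int
    chromatid_id: np.ndarray | None = None
    annotations: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chromatid_id is None:
            self.chromatid_id = np.zeros(len(self.genomic_bp), dtype=np.int32)
        for cid in np.unique(self.chromatid_id):
            g = self.genomic_bp[self.chromatid_id == cid]
            if np.any(np.diff(g) <= 0):
                raise ValueError("genomic coordinates must be strictly increasing")

    @property
    def n_beads(self) -> int:
        return len(self.genomic_bp)

    def select(self, flag: str) -> np.ndarray:
        return self.xyz[self.annotations[flag].astype(bool)]


@dataclass
class CohesiveLinkSet:
    """Symmetric cohesive-cohesin tether positions on a sister pair (bp)."""

    positions_bp: np.ndarray

    def __post_init__(self) -> None:
        self.positions_bp = np.sort(np.asarray(self.positions_bp, dtype=float))

    def __len__(self) -> int:
        return len(self.positions_bp)

    def spacing_stats(self) -> dict:
        if len(self.positions_bp) < 2:
            return {"mean_bp": None, "cv": None}
        d = np.diff(self.positions_bp)
        return {"mean_bp": float(np.mean(d)),
                "cv": float(np.std(d) / np.mean(d)) if np.mean(d) > 0 else None}


# --------------------------------------------------------------------- loops

def segments_from_loops(loop_array: np.ndarray, genome_bp: float
                        ) -> list[tuple[float, float, bool]]:
    """Partition the genome into (start, end, is_loop) segments.

    Chromatin between loops (1D gaps) becomes backbone linker segments.
    Overlapping loops are rejected: the builders assume consecutive arrays.
    """
    segs: list[tuple[float, float, bool]] = []
    cursor = 0.0
    loops = np.asarray(loop_array, dtype=float).reshape(-1, 2)
    for a, b in loops[np.argsort(loops[:, 0])] if len(loops) else []:
        if a < cursor - 1e-6:
            raise ValueError("loop array is not consecutive (overlapping loops)")
        if a > cursor:
            segs.append((cursor, a, False))
        if b > a:
            segs.append((a, b, True))
        cursor = b
    if cursor < genome_bp:
        segs.append((cursor, genome_bp, False))
    return segs


def _ou_path(rng: np.random.Generator, n: int, sigma: float, corr_steps: float
             ) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples along the backbone."""
    if sigma <= 0 or n == 0:
        return np.zeros(n)
    a = np.exp(-1.0 / max(corr_steps, 1e-9))
    x = np.empty(n)
    x[0] = rng.normal(0, sigma)
    eps = rng.standard_normal(max(n - 1, 0)) * sigma * np.sqrt(1 - a * a)
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i - 1]
    return x


def _anchored_walk(rng: np.random.Generator, guide_pts: np.ndarray, step: float,
                   pull: float) -> np.ndarray:
    """Random walk with fixed step length, attracted to a guide path."""
    n = len(guide_pts)
    out = np.empty_like(guide_pts)
    out[0] = guide_pts[0]
    xi = rng.standard_normal((n - 1, 3))
    for i in range(n - 1):
        d = xi[i] + pull * (guide_pts[i + 1] - out[i]) / step
        d /= np.linalg.norm(d)
        out[i + 1] = out[i] + step * d
    return out


def _bridges(rng: np.random.Generator, anchors: np.ndarray,
             seg_beads: Sequence[int], widths: Sequence[float]) -> np.ndarray:
    """Gaussian-bridge interiors between consecutive anchors."""
    out = [anchors[0:1]]
    for i, n in enumerate(seg_beads):
        if n == 0:
            continue
        b = widths[i]
        steps = rng.standard_normal((n, 3)) * b / np.sqrt(3)
        w = np.cumsum(steps, axis=0)
        t = (np.arange(1, n + 1) / n)[:, None]
        out.append(anchors[i] + w - t * (w[-1] - (anchors[i + 1] - anchors[i])))
    return np.vstack(out)


def _confine_cylinder(xyz: np.ndarray, radius: float, z_max: float) -> None:
    """Fold beads back inside the cylinder (in place)."""
    r = np.hypot(xyz[:, 0], xyz[:, 1])
    over = r > radius
    f = np.clip((2 * radius - r[over]) / r[over], 0.05, None)
    xyz[over, 0] *= f
    xyz[over, 1] *= f
    z = np.abs(xyz[:, 2])
    xyz[:, 2] = np.clip(z_max - np.abs(z_max - z), 0.0, z_max)


def _density_cap(rng: np.random.Generator, xyz: np.ndarray, cell_nm: float,
                 cap_beads_per_cell: float, max_retries: int = 2) -> None:
    """Spread beads out of grossly over-occupied grid cells (in place).

    Cells holding more than ``cap_beads_per_cell`` beads have their excess
    re-jittered by one cell width; a light-touch surrogate for excluded
    volume that leaves regions at or below the target density untouched.
    """
    cap = max(cap_beads_per_cell, 2.0)
    for _ in range(max_retries):
        keys = np.floor(xyz / cell_nm).astype(np.int64)
        _, inv, counts = np.unique(keys, axis=0, return_inverse=True,
                                   return_counts=True)
        crowded = counts[inv] > cap
        if not np.any(crowded):
            return
        idx = np.flatnonzero(crowded)
        keep = rng.random(len(idx)) < cap / counts[inv][idx]
        idx = idx[~keep]
        if len(idx) == 0:
            return
        xyz[idx] += rng.standard_normal((len(idx), 3)) * cell_nm


def _build_on_guide(loop_array: np.ndarray, params: ChromatidParams,
                    genome_bp: float, guide_fn: Callable[[np.ndarray], np.ndarray],
                    seed: int, confine: bool, reach_nm: float,
                    chromatid_id: int = 0, offset: np.ndarray | None = None,
                    link_points: dict[float, np.ndarray] | None = None,
                    anchored: bool = True,
                    width_factor: float | None = None) -> Conformation:
    """Shared backbone+loops construction for all builders.

    ``link_points`` optionally pins the mid-loop bead nearest a genomic
    position to a given 3D point (used for cohesive links in sister pairs).
    """
    rng = np.random.default_rng(seed)
    segs = segments_from_loops(loop_array, genome_bp)
    bead = params.bead_bp
    bounds = np.array([s[0] for s in segs] + [genome_bp])
    anchors_guide = guide_fn(bounds)
    if anchored:
        anchors = _anchored_walk(rng, anchors_guide, params.gap_nm,
                                 params.guide_pull)
    else:
        anchors = anchors_guide
    if offset is not None:
        anchors = anchors + offset
    seg_beads = [max(int(round((e - s) / bead)) - (0 if i < len(segs) - 1 else 1), 1)
                 for i, (s, e, _) in enumerate(segs)]
    wf = params.loop_width_factor if width_factor is None else width_factor
    widths = []
    for (s, e, is_loop), n in zip(segs, seg_beads):
        if is_loop:
            widths.append(wf * reach_nm / np.sqrt(max(n, 2)))
        else:
            widths.append(params.bead_diameter_nm)
    xyz = _bridges(rng, anchors, seg_beads, widths)
    genomic = np.concatenate(
        [[segs[0][0]]] + [np.linspace(s, e, n + 1)[1:] for (s, e, _), n
                          in zip(segs, seg_beads)]
    )
    is_anchor = np.zeros(len(genomic), dtype=bool)
    cum = np.cumsum([0] + seg_beads)
    is_anchor[cum[cum < len(genomic)]] = True
    is_loop_bead = np.zeros(len(genomic), dtype=bool)
    for (s, e, is_loop), i0, i1 in zip(segs, cum[:-1], cum[1:]):
        if is_loop:
            is_loop_bead[i0 + 1:i1 + 1] = True
    if link_points:
        for g, pt in link_points.items():
            j = int(np.argmin(np.abs(genomic - g)))
            xyz[j] = pt + rng.standard_normal(3) * params.bead_diameter_nm / 2
    if confine:
        R = params.cylinder_radius_nm(genome_bp)
        Lz = params.axis_length_nm(genome_bp)
        center = offset if offset is not None else np.zeros(3)
        local = xyz - center
        _confine_cylinder(local, R, Lz)
        xyz = local + center
        # excluded-volume surrogate; only meaningful under confinement,
        # where crowding above the target density can actually occur
        cell = 2.0 * params.bead_diameter_nm
        cap = 3.0 * params.volume_density_mb_um3 * (cell / 1000.0) ** 3 \
            / (params.bead_bp / 1e6)
        _density_cap(rng, xyz, cell, cap)
    conf = Conformation(
        genomic_bp=genomic, xyz=xyz, bead_bp=bead,
        chromatid_id=np.full(len(genomic), chromatid_id, dtype=np.int32),
        annotations={"loop_anchor": is_anchor, "loop_interior": is_loop_bead},
        meta={"seed": seed, "loop_array": np.asarray(loop_array, dtype=float),
              "genome_bp": genome_bp, "params": params},
    )
    return conf


# ------------------------------------------------------------------ builders

def build_bottlebrush(loop_array: np.ndarray, params: ChromatidParams,
                      genome_bp: float, seed: int = 0) -> Conformation:
    """Loop array packed into a straight cylindrical chromatid.

    Loop-anchor beads (the condensin scaffold) wander near the cylinder
    axis within ``scaffold_radius_fraction`` of the cylinder radius; loop
    interiors are Gaussian bridges wide enough to fill the cross section.
    """
    R = params.cylinder_radius_nm(genome_bp)
    Lz = params.axis_length_nm(genome_bp)
    r_sc = params.scaffold_radius_fraction * R
    if params.gap_nm >= 2 * R:
        raise ValueError("gap size exceeds chromatid diameter; "
                         "loops cannot fit the cylinder cross-section")
    rng0 = np.random.default_rng(seed)
    phi0 = rng0.uniform(0, 2 * np.pi)

    def guide(g: np.ndarray) -> np.ndarray:
        z = np.asarray(g) / genome_bp * Lz
        # slow wander of the scaffold inside the scaffold radius
        phi = phi0 + 2 * np.pi * np.asarray(g) / genome_bp
        return np.stack([r_sc * np.cos(phi) * 0.5, r_sc * np.sin(phi) * 0.5, z],
                        axis=-1)

    return _build_on_guide(loop_array, params, genome_bp, guide, seed,
                           confine=True, reach_nm=R)


def apply_helical_scaffold(conf: Conformation, params: ChromatidParams | None = None
                           ) -> Conformation:
    """Re-draw a bottlebrush with its backbone nudged onto an irregular helix.

    The winding number is fixed at genome length / turn length; the helical
    guide carries correlated axial and angular jitter (an irregular, not
    crystalline, spiral) and the backbone only loosely follows it. Ends map
    to the opposite caps of the cylinder. This is a constructive re-draw
    seeded by the conformation's own seed, not a perturbation of bead
    coordinates.
    """
    params = params or conf.meta["params"]
    genome_bp = conf.meta["genome_bp"]
    loop_array = conf.meta["loop_array"]
    seed = conf.meta["seed"]
    if params.turn_mb is None or not np.isfinite(params.turn_mb):
        return build_bottlebrush(loop_array, params, genome_bp, seed)
    if params.turn_mb >= genome_bp / 1e6:
        import warnings
        warnings.warn("turn length >= chromatid length: fewer than one turn")
    R = params.cylinder_radius_nm(genome_bp)
    Lz = params.axis_length_nm(genome_bp)
    r_sc = params.scaffold_radius_fraction * R
    rng0 = np.random.default_rng(seed + 104729)
    phi0 = rng0.uniform(0, 2 * np.pi)
    n_loops = max(len(loop_array), 2)
    corr = params.jitter_corr_mb / max(genome_bp / 1e6 / n_loops, 1e-9)
    dz_tab = _ou_path(rng0, n_loops + 1, params.helix_z_jitter_nm, corr)
    dphi_tab = _ou_path(rng0, n_loops + 1, params.helix_phase_jitter_rad, corr)
    g_tab = np.linspace(0, genome_bp, n_loops + 1)

    def guide(g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        dz = np.interp(g, g_tab, dz_tab)
        dphi = np.interp(g, g_tab, dphi_tab)
        phi = 2 * np.pi * g / (params.turn_mb * 1e6) + phi0 + dphi
        z = np.clip(g / genome_bp * Lz + dz, 0, Lz)
        return np.stack([r_sc * np.cos(phi), r_sc * np.sin(phi), z], axis=-1)

    return _build_on_guide(loop_array, params, genome_bp, guide, seed,
                           confine=True, reach_nm=R)


def build_periodic_random_walk(loop_array: np.ndarray, params: ChromatidParams,
                               genome_bp: float, seed: int = 0) -> Conformation:
    """Loop array on a weakly stretched random-walk backbone (no cylinder).

    The backbone is a worm-like path of loop anchors (step = gap size,
    natural persistence ~ the brush cross-section radius) whose end-to-end
    vector is then set to ``end_to_end_um`` by linear reallocation — a
    stretched random walk. Loop interiors fill the brush cross-section
    set by the volume-density closure.
    """
    segs = segments_from_loops(loop_array, genome_bp)
    # guide step per segment: a gap for loops (anchors adjacent), the
    # random-walk span of the bare fiber for unlooped linkers
    step_len = np.array([
        params.gap_nm if is_loop else max(
            params.bead_diameter_nm * np.sqrt(max((e - s) / params.bead_bp, 1.0)),
            params.gap_nm)
        for (s, e, is_loop) in segs
    ])
    contour_nm = float(step_len.sum())
    e2e_nm = params.end_to_end_um * 1000.0
    if e2e_nm > contour_nm:
        raise ValueError("end-to-end distance exceeds backbone contour length")
    r_bb = params.brush_radius_nm
    lp = params.backbone_persistence_factor * r_bb
    rng0 = np.random.default_rng(seed + 7919)
    sig = np.sqrt(2 * params.gap_nm / lp)

    def guide(bounds: np.ndarray) -> np.ndarray:
        n = len(bounds) - 1
        d = np.array([0.0, 0.0, 1.0])
        dirs = np.empty((n, 3))
        for i in range(n):
            k = rng0.standard_normal(3)
            k -= (k @ d) * d
            nk = np.linalg.norm(k)
            d = d + k * (sig * rng0.standard_normal() / max(nk, 1e-12))
            d /= np.linalg.norm(d)
            dirs[i] = d
        steps = dirs * step_len[:, None]
        pts = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
        if e2e_nm > 0:
            # stretch by reallocating only the longitudinal component: a
            # per-chain constant drift along z sets the end-to-end
            # extension; transverse fluctuations stay free (a full 3D
            # bridge would pin them at the chain ends and distort large-s
            # contact statistics)
            t = np.arange(len(pts)) / max(len(pts) - 1, 1)
            pts[:, 2] += t * (e2e_nm - pts[-1, 2])
        return pts

    # bridge width such that the bead-averaged transverse spread realizes
    # the uniform-disc-equivalent brush radius exactly (sigma^2 = r_bb^2/4)
    return _build_on_guide(loop_array, params, genome_bp, guide, seed,
                           confine=False, reach_nm=r_bb, anchored=False,
                           width_factor=3.0 / np.sqrt(2.0))


def build_chromatid(loop_array: np.ndarray, params: ChromatidParams,
                    genome_bp: float, seed: int = 0) -> Conformation:
    """Dispatch on ``params.helix_mode``."""
    if params.helix_mode == "periodic_random_walk":
        return build_periodic_random_walk(loop_array, params, genome_bp, seed)
    conf = build_bottlebrush(loop_array, params, genome_bp, seed)
    if params.turn_mb is not None and np.isfinite(params.turn_mb):
        conf = apply_helical_scaffold(conf, params)
    return conf


def build_sister_pair(loops1: np.ndarray, loops2: np.ndarray,
                      links: CohesiveLinkSet, mode: str,
                      params: ChromatidParams, genome_bp: float,
                      seed: int = 0) -> Conformation:
    """Two cohesed sister chromatids under bypass vs stall condensin rules.

    bypass: each sister forms its own bottlebrush axis; cohesive links sit
    inside loops (distal) and are pinned near the inter-sister interface.
    stall: loop arrays are truncated at link positions (condensins cannot
    pass), links sit at loop bases, and the two sisters share one axis.
    """
    if mode not in ("bypass", "stall"):
        raise ValueError("mode must be 'bypass' or 'stall'")
    pos = np.asarray(links.positions_bp, dtype=float)
    if len(pos) and (pos.min() < 0 or pos.max() > genome_bp):
        raise ValueError("cohesive links outside chromatid range")
    R = params.cylinder_radius_nm(genome_bp)
    Lz = params.axis_length_nm(genome_bp)
    rng = np.random.default_rng(seed)
    if mode == "stall":
        loops1 = _truncate_at_links(loops1, pos)
        loops2 = _truncate_at_links(loops2, pos)
        offsets = [np.zeros(3), np.zeros(3)]
        link_pts = {
            g: np.array([0, 0, g / genome_bp * Lz])
            + rng.standard_normal(3) * params.gap_nm
            for g in pos
        }
        link_maps = [link_pts, link_pts]
    else:
        sep = 1.6 * R
        offsets = [np.array([-sep / 2, 0, 0]), np.array([+sep / 2, 0, 0])]
        link_maps = [{}, {}]
        for g in pos:
            pt = np.array([0, 0, g / genome_bp * Lz]) \
                + rng.standard_normal(3) * (0.25 * R)
            link_maps[0][g] = pt
            link_maps[1][g] = pt
    confs = []
    for cid, (loops, off, lmap) in enumerate(zip((loops1, loops2), offsets,
                                                 link_maps)):
        r_sc = params.scaffold_radius_fraction * R
        phi0 = rng.uniform(0, 2 * np.pi)

        def guide(g: np.ndarray, _phi0=phi0, _off=off) -> np.ndarray:
            g = np.asarray(g, dtype=float)
            z = g / genome_bp * Lz
            phi = _phi0 + 2 * np.pi * g / genome_bp
            return np.stack([
                _off[0] + 0.5 * r_sc * np.cos(phi),
                _off[1] + 0.5 * r_sc * np.sin(phi), z], axis=-1)

        conf = _build_on_guide(loops, params, genome_bp, guide,
                               seed + 13 * cid, confine=False, reach_nm=R,
                               chromatid_id=cid, link_points=lmap)
        confs.append(conf)
    genomic = np.concatenate([c.genomic_bp for c in confs])
    xyz = np.vstack([c.xyz for c in confs])
    cids = np.concatenate([c.chromatid_id for c in confs])
    ann = {k: np.concatenate([c.annotations[k] for c in confs])
           for k in confs[0].annotations}
    link_flag = np.zeros(len(genomic), dtype=bool)
    for cid, c in enumerate(confs):
        base = 0 if cid == 0 else confs[0].n_beads
        for g in pos:
            j = int(np.argmin(np.abs(c.genomic_bp - g)))
            link_flag[base + j] = True
    ann["cohesive_cohesin"] = link_flag
    return Conformation(genomic_bp=genomic, xyz=xyz, bead_bp=params.bead_bp,
                        chromatid_id=cids, annotations=ann,
                        meta={"mode": mode, "genome_bp": genome_bp,
                              "params": params, "seed": seed})


def _truncate_at_links(loop_array: np.ndarray, link_pos: np.ndarray
                       ) -> np.ndarray:
    """Split loops at cohesive-link positions (stall mode)."""
    out = []
    for a, b in np.asarray(loop_array, dtype=float).reshape(-1, 2):
        cuts = np.sort(link_pos[(link_pos > a) & (link_pos < b)])
        edges = np.concatenate([[a], cuts, [b]])
        for i in range(len(edges) - 1):
            if edges[i + 1] > edges[i]:
                out.append((edges[i], edges[i + 1]))
    return np.array(out, dtype=float).reshape(-1, 2)


def build_nested_bottlebrush(loops_outer: np.ndarray, loops_inner: np.ndarray,
                             params_outer: ChromatidParams,
                             params_inner: ChromatidParams,
                             genome_bp: float, seed: int = 0) -> Conformation:
    """Two-level loop array: inner (condensin I) loops inside outer
    (condensin II) loops, on the outer model's backbone geometry.

    Outer anchors follow the outer model's (helical) scaffold; between
    consecutive outer anchors, the chain of inner-loop anchors is a
    Gaussian bridge filling the outer loop's territory; inner loop
    interiors are narrow bridges filling the inner brush cross-section.
    """
    rng = np.random.default_rng(seed)
    outer = build_chromatid(loops_outer, params_outer, genome_bp, seed)
    anchor_sel = outer.annotations["loop_anchor"].astype(bool)
    anchor_g = outer.genomic_bp[anchor_sel]
    anchor_xyz = outer.xyz[anchor_sel]
    R = params_outer.cylinder_radius_nm(genome_bp)
    inner = np.asarray(loops_inner, dtype=float).reshape(-1, 2)
    bounds = np.unique(np.concatenate([inner.ravel(), anchor_g, [0, genome_bp]]))
    # 3D positions of all (outer + inner) anchors: bridge between outer anchors
    pts = np.empty((len(bounds), 3))
    outer_idx = np.searchsorted(bounds, anchor_g)
    pts[outer_idx] = anchor_xyz
    for k in range(len(anchor_g) - 1):
        i0, i1 = outer_idx[k], outer_idx[k + 1]
        n = i1 - i0
        if n <= 1:
            continue
        b = params_outer.loop_width_factor * R / np.sqrt(n)
        steps = rng.standard_normal((n, 3)) * b / np.sqrt(3)
        w = np.cumsum(steps, axis=0)
        t = (np.arange(1, n + 1) / n)[:, None]
        pts[i0 + 1:i1 + 1] = pts[i0] + w - t * (w[-1] - (pts[i1] - pts[i0]))
    # inner loop interiors around the anchor chain
    bead = params_inner.bead_bp
    seg_beads = [max(int(round((bounds[i + 1] - bounds[i]) / bead)), 1)
                 for i in range(len(bounds) - 1)]
    r_in = params_inner.brush_radius_nm
    widths = [params_inner.loop_width_factor * r_in / np.sqrt(max(n, 2))
              for n in seg_beads]
    xyz = _bridges(rng, pts, seg_beads, widths)
    genomic = np.concatenate(
        [[bounds[0]]] + [np.linspace(bounds[i], bounds[i + 1], n + 1)[1:]
                         for i, n in enumerate(seg_beads)]
    )
    _confine_cylinder(xyz, R, params_outer.axis_length_nm(genome_bp))
    cell = 2.0 * params_outer.bead_diameter_nm
    cap = 3.0 * params_outer.volume_density_mb_um3 * (cell / 1000.0) ** 3 \
        / (bead / 1e6)
    _density_cap(rng, xyz, cell, cap)
    is_anchor = np.zeros(len(genomic), dtype=bool)
    cum = np.cumsum([0] + seg_beads)
    is_anchor[cum[cum < len(genomic)]] = True
    return Conformation(
        genomic_bp=genomic, xyz=xyz, bead_bp=bead,
        annotations={"loop_anchor": is_anchor,
                     "loop_interior": ~is_anchor},
        meta={"seed": seed, "loop_array": inner, "outer_loops": loops_outer,
              "genome_bp": genome_bp, "params": params_outer,
              "params_inner": params_inner},
    )


# ------------------------------------------------------------------ analysis

def realized_volume_density(conf: Conformation, cell_factor: float = 1.5
                            ) -> float:
    """Realized chromatin density (Mb/um^3) of a built conformation.

    For cylinder-confined modes this is the mass inside the design cylinder
    over the cylinder volume (a leakage check — the radius itself derives
    from the target density). For the unconfined stretched-brush mode it is
    the brush-tube density: the linear chromatin mass along the backbone
    divided by the uniform-disc-equivalent cross-section realized by the
    loops (radius = 2x the per-axis transverse spread of loop beads about
    their anchors). Backbone folding at larger scales is not counted; the
    EM density constrains the brush tube.
    """
    params: ChromatidParams = conf.meta["params"]
    genome_bp = conf.meta.get("genome_bp", conf.genomic_bp.max())
    if params.helix_mode != "periodic_random_walk":
        R = params.cylinder_radius_nm(genome_bp)
        Lz = params.axis_length_nm(genome_bp)
        r = np.hypot(conf.xyz[:, 0], conf.xyz[:, 1])
        inside = (r <= R * 1.001) & (conf.xyz[:, 2] >= -1) \
            & (conf.xyz[:, 2] <= Lz + 1)
        mass_mb = inside.sum() * conf.bead_bp / 1e6
        vol_um3 = np.pi * (R / 1000.0) ** 2 * (Lz / 1000.0)
        return mass_mb / vol_um3
    anchor_sel = conf.annotations["loop_anchor"].astype(bool)
    anchor_g = conf.genomic_bp[anchor_sel]
    anchor_xyz = conf.xyz[anchor_sel]
    interior = conf.annotations["loop_interior"].astype(bool)
    idx = np.clip(np.searchsorted(anchor_g, conf.genomic_bp[interior]) - 1,
                  0, len(anchor_g) - 1)
    d2 = np.sum((conf.xyz[interior] - anchor_xyz[idx]) ** 2, axis=1)
    sigma2_per_axis = np.mean(d2) / 3.0
    r_eff_um = 2.0 * np.sqrt(sigma2_per_axis) / 1000.0
    lin_mb_per_um = (params.loop_bp / 1e6) / (params.gap_nm / 1000.0)
    return lin_mb_per_um / (np.pi * r_eff_um ** 2)


def cross_section_profile(conf: Conformation,
                          markers: Sequence[str] = ("dna", "loop_anchor"),
                          axis_direction: np.ndarray | None = None,
                          n_bins: int = 40) -> dict[str, dict]:
    """Line-scan histograms of markers across the chromatid axis.

    The axis is the principal component of the loop-anchor (scaffold) beads
    unless given; profiles are of the perpendicular offset along the most
    informative transverse direction (the inter-axis direction for sister
    pairs). Histograms are normalized to unit area; peak position and full
    width at half maximum are reported.
    """
    anchors = conf.xyz[conf.annotations["loop_anchor"].astype(bool)]
    if len(anchors) < 100:
        import warnings
        warnings.warn("fewer than 100 annotated beads; profile bins widened")
        n_bins = max(n_bins // 2, 10)
    center = anchors.mean(axis=0)
    if axis_direction is None:
        # per-chromatid principal axes, averaged: robust for sister pairs,
        # where the inter-axis offset would otherwise dominate the PCA
        axes = []
        for cid in np.unique(conf.chromatid_id):
            sel = conf.annotations["loop_anchor"].astype(bool) \
                & (conf.chromatid_id == cid)
            pts = conf.xyz[sel]
            u, s, vt = np.linalg.svd(pts - pts.mean(axis=0),
                                     full_matrices=False)
            a = vt[0]
            if axes and a @ axes[0] < 0:
                a = -a
            axes.append(a)
        axis = np.mean(axes, axis=0)
        axis = axis / np.linalg.norm(axis)
    else:
        axis = np.asarray(axis_direction, dtype=float)
        axis = axis / np.linalg.norm(axis)
    rel = conf.xyz - center
    perp = rel - np.outer(rel @ axis, axis)
    # transverse direction: spread-maximizing for two-chromatid input,
    # otherwise an arbitrary perpendicular
    if conf.chromatid_id is not None and len(np.unique(conf.chromatid_id)) > 1:
        c0 = perp[conf.chromatid_id == 0].mean(axis=0)
        c1 = perp[conf.chromatid_id == 1].mean(axis=0)
        t = c1 - c0
        if np.linalg.norm(t) < 1e-9:
            t = np.array([1.0, 0.0, 0.0])
    else:
        u, s, vt = np.linalg.svd(perp, full_matrices=False)
        t = vt[0]
    t = t / np.linalg.norm(t)
    coord = perp @ t
    lim = np.percentile(np.abs(coord), 99.5)
    edges = np.linspace(-lim, lim, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    out: dict[str, dict] = {}
    for marker in markers:
        if marker == "dna":
            sel = np.ones(conf.n_beads, dtype=bool)
        else:
            sel = conf.annotations[marker].astype(bool)
        h, _ = np.histogram(coord[sel], edges)
        area = h.sum() * (edges[1] - edges[0])
        dens = h / area if area > 0 else h.astype(float)
        out[marker] = {
            "bins_nm": mids, "density": dens,
            "peak_nm": float(mids[np.argmax(dens)]) if dens.max() > 0 else None,
            "fwhm_nm": _fwhm(mids, dens),
        }
    return out


def _fwhm(x: np.ndarray, y: np.ndarray) -> float | None:
    if y.max() <= 0:
        return None
    half = y.max() / 2.0
    above = np.flatnonzero(y >= half)
    return float(x[above[-1]] - x[above[0]]) if len(above) else None
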