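"""Compartmentalized neuron morphology.

A morphology is a rooted tree of cylindrical compartments (parent links,
length, diameter, region tag) in Hines order (every parent precedes its
children), plus derived geometry: membrane area, path distance to the soma,
and branch (unbranched section) membership.

A deterministic synthetic L5-pyramidal-like template stands in for a
reconstructed cell: a soma with an axon stub, several branched basal
dendrites, an apical trunk with oblique branches, and a nexus that splits
into a large tuft.  Default cable totals match the reference cell the
synapse-density estimates assume (7440 um apical, 4649 um basal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Morphology", "MorphologyParams", "build_synthetic_morphology",
           "read_swc", "REGIONS"]

REGIONS = ("soma", "axon", "basal", "apical_trunk", "nexus", "tuft")
_SWC_TYPE = {"soma": 1, "axon": 2, "basal": 3,
             "apical_trunk": 4, "nexus": 4, "tuft": 4}
_SUBTREE = {"soma": "soma", "axon": "axon", "basal": "basal",
            "apical_trunk": "apical", "nexus": "apical", "tuft": "apical"}


@dataclass
class _Section:
    """An unbranched cable section before compartmentalization."""
    name: str
    parent: int          # index into section list, -1 for root
    length: float        # um
    diam0: float         # um at proximal end
    diam1: float         # um at distal end
    region: str
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))


class Morphology:
    """Array-backed compartment tree.

    Attributes (all length ``n_comp``, Hines-ordered)
    -------------------------------------------------
    parent : int array, -1 at the root (soma)
    length, diam : um
    region : object array over ``REGIONS``
    branch_id : id of the unbranched section a compartment belongs to
    path_dist : um, path distance from the soma center to the compartment center
    xyz : (n, 3) compartment-center coordinates (layout only)
    """

    def __init__(self, parent, length, diam, region, branch_id, xyz=None):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.diam = np.asarray(diam, dtype=float)
        self.region = np.asarray(region, dtype=object)
        self.branch_id = np.asarray(branch_id, dtype=int)
        n = self.parent.size
        if not (self.length.size == self.diam.size == self.region.size == n):
            raise ValueError("inconsistent array lengths")
        if np.sum(self.parent < 0) != 1 or self.parent[0] != -1:
            raise ValueError("exactly one root (index 0) required")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("compartments must be in parent-before-child order")
        if np.any(self.length <= 0) or np.any(self.diam <= 0):
            raise ValueError("lengths and diameters must be positive")
        bad = set(self.region) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region tags: {bad}")
        self.xyz = (np.asarray(xyz, dtype=float) if xyz is not None
                    else np.zeros((n, 3)))
        self._compute_path_dist()

    @property
    def n_comp(self) -> int:
        return self.parent.size

    @property
    def subtree(self) -> np.ndarray:
        """'soma' | 'axon' | 'basal' | 'apical' per compartment."""
        return np.array([_SUBTREE[r] for r in self.region], dtype=object)

    @property
    def area(self) -> np.ndarray:
        """Lateral membrane area per compartment, cm^2."""
        return np.pi * self.diam * self.length * 1e-8

    def _compute_path_dist(self) -> None:
        # distance from soma center to compartment center along the cable
        d = np.zeros(self.n_comp)
        for i in range(1, self.n_comp):
            p = self.parent[i]
            d[i] = d[p] + 0.5 * self.length[p] + 0.5 * self.length[i]
        d[self.region == "soma"] = 0.0
        self.path_dist = d

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_comp)]
        for i in range(1, self.n_comp):
            ch[self.parent[i]].append(i)
        return ch

    def total_length(self, subtree: str | None = None,
                     region: str | None = None) -> float:
        """Total cable length (um), optionally restricted."""
        mask = np.ones(self.n_comp, dtype=bool)
        if subtree is not None:
            mask &= self.subtree == subtree
        if region is not None:
            mask &= self.region == region
        return float(self.length[mask].sum())

    def dendritic_mask(self) -> np.ndarray:
        return np.isin(self.region, ("basal", "apical_trunk", "nexus", "tuft"))

    def perisomatic_mask(self, radius: float = 100.0) -> np.ndarray:
        """Soma plus dendritic compartments within ``radius`` um path distance."""
        return ((self.region == "soma") |
                (self.dendritic_mask() & (self.path_dist <= radius)))

    def nexus_index(self) -> int:
        """Representative hot-zone compartment (end of the nexus section)."""
        idx = np.nonzero(self.region == "nexus")[0]
        if idx.size == 0:
            raise ValueError("morphology has no nexus region")
        first_branch = self.branch_id[idx[0]]
        return int(idx[self.branch_id[idx] == first_branch][-1])

    def soma_index(self) -> int:
        return 0

    # ------------------------------------------------------------------ I/O
    def to_swc(self, path, sidecar: bool = True) -> None:
        """Write standard 7-column SWC (1-based ids).

        Region subtags beyond the four SWC type codes go to a sidecar table
        ``<path>.regions.csv`` (columns: swc_id, region).
        """
        rows = []
        for i in range(self.n_comp):
            r = 0.5 * self.diam[i]
            x, y, z = self.xyz[i]
            rows.append((i + 1, _SWC_TYPE[self.region[i]], x, y, z, r,
                         self.parent[i] + 1 if self.parent[i] >= 0 else -1))
        with open(path, "w") as fh:
            fh.write("# SWC export; one point per compartment (distal end)\n")
            fh.write("# root_length_um: %.6f\n" % self.length[0])
            for row in rows:
                fh.write("%d %d %.6f %.6f %.6f %.6f %d\n" % row)
        if sidecar:
            pd.DataFrame({
                "swc_id": np.arange(1, self.n_comp + 1),
                "region": self.region,
                "branch_id": self.branch_id,
            }).to_csv(str(path) + ".regions.csv", index=False)


def read_swc(path, sidecar: bool = True) -> Morphology:
    """Read an SWC written by :meth:`Morphology.to_swc` (or compatible).

    Compartment length is the distance to the parent point (the root keeps
    its radius-derived length); without a sidecar, regions fall back to the
    SWC type code (all apical points tagged ``apical_trunk``).
    """
    root_len = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# root_length_um:"):
                root_len = float(line.split(":")[1])
            if not line.startswith("#"):
                break
    raw = np.loadtxt(path, comments="#", ndmin=2)
    ids = raw[:, 0].astype(int)
    order = np.argsort(ids)
    raw = raw[order]
    id_map = {int(r[0]): k for k, r in enumerate(raw)}
    parent = np.array([id_map[int(p)] if p > 0 else -1 for p in raw[:, 6]])
    xyz = raw[:, 2:5]
    diam = 2.0 * raw[:, 5]
    n = len(raw)
    length = np.zeros(n)
    for i in range(n):
        if parent[i] < 0:
            # spherical-soma convention unless the writer recorded the length
            length[i] = root_len if root_len is not None else diam[i]
        else:
            length[i] = np.linalg.norm(xyz[i] - xyz[parent[i]])
            if length[i] <= 0:
                length[i] = 1e-3
    inv_type = {1: "soma", 2: "axon", 3: "basal", 4: "apical_trunk"}
    region = np.array([inv_type.get(int(t), "basal") for t in raw[:, 1]],
                      dtype=object)
    branch_id = np.zeros(n, dtype=int)
    import os
    side = str(path) + ".regions.csv"
    if sidecar and os.path.exists(side):
        tab = pd.read_csv(side)
        region = tab["region"].to_numpy(dtype=object)
        branch_id = tab["branch_id"].to_numpy(dtype=int)
    return Morphology(parent, length, diam, region, branch_id, xyz)


@dataclass
class MorphologyParams:
    """Template parameters for the synthetic L5-like cell.

    ``scale`` multiplies every section length (diameters fixed), so reduced
    desk-scale cells keep the branching structure and per-um densities of the
    full template.  ``jitter`` adds seeded relative length noise per section;
    subtree totals are renormalized afterwards so apical/basal cable totals
    are preserved exactly.
    """
    apical_total: float = 7440.0
    basal_total: float = 4649.0
    n_basal: int = 8
    trunk_length: float = 600.0
    n_oblique: int = 8
    oblique_length: float = 115.0
    nexus_length: float = 20.0
    soma_length: float = 25.0
    soma_diam: float = 25.0
    axon_length: float = 60.0
    axon_diam: float = 1.5
    seg_len: float = 20.0
    scale: float = 1.0
    diam_scale: float | None = None   # default sqrt(scale), floor 0.3 um
    jitter: float = 0.0

    def scaled(self, scale: float) -> "MorphologyParams":
        return replace(self, scale=scale)


def _basal_sections(p: MorphologyParams, rng) -> list[tuple]:
    """(parent_key, length, d0, d1, region) tuples for one basal template."""
    # primary -> 2 children -> 4 grandchildren per primary dendrite
    total_t = p.n_basal * (60.0 + 2 * 90.0 + 4 * 85.0)
    f = p.basal_total / total_t
    out = []
    for b in range(p.n_basal):
        out.append((f"soma", f"bas{b}p", 60.0 * f, 2.5, 1.6, "basal"))
        for c in range(2):
            out.append((f"bas{b}p", f"bas{b}c{c}", 90.0 * f, 1.6, 1.0, "basal"))
            for g in range(2):
                out.append((f"bas{b}c{c}", f"bas{b}c{c}g{g}", 85.0 * f,
                            1.0, 0.7, "basal"))
    return out


def _apical_sections(p: MorphologyParams, rng) -> list[tuple]:
    out = []
    non_tuft = (p.trunk_length + p.n_oblique * p.oblique_length
                + p.nexus_length)
    tuft_total = p.apical_total - non_tuft
    if tuft_total <= 0:
        raise ValueError("apical_total too small for trunk/oblique template")
    # trunk split into n_oblique pieces so obliques attach along its length
    n_seg = max(p.n_oblique, 1)
    seg = p.trunk_length / n_seg
    prev = "soma"
    for k in range(n_seg):
        d0 = 4.0 - 1.4 * k / n_seg
        d1 = 4.0 - 1.4 * (k + 1) / n_seg
        out.append((prev, f"trunk{k}", seg, d0, d1, "apical_trunk"))
        prev = f"trunk{k}"
        out.append((prev, f"obl{k}", p.oblique_length, 1.2, 0.8,
                    "apical_trunk"))
    out.append((prev, "nexus", p.nexus_length, 2.6, 2.6, "nexus"))
    # tuft: 2 -> 4 -> 8 -> 16 binary tree; template lengths 250/300/300/L
    t16 = (tuft_total - (2 * 250.0 + 4 * 300.0 + 8 * 300.0)) / 16.0
    if t16 <= 5.0:
        # small scaled cells: proportional shrink of the 3-level template
        f = tuft_total / (2 * 250.0 + 4 * 300.0 + 8 * 300.0)
        for a in range(2):
            # first-order tuft branches belong to the nexus Ca2+ hot zone
            out.append(("nexus", f"tuft{a}", 250.0 * f, 1.6, 1.2, "nexus"))
            for b in range(2):
                out.append((f"tuft{a}", f"tuft{a}{b}", 300.0 * f, 1.2, 0.9, "tuft"))
                for c in range(2):
                    out.append((f"tuft{a}{b}", f"tuft{a}{b}{c}", 300.0 * f,
                                0.9, 0.7, "tuft"))
    else:
        for a in range(2):
            # first-order tuft branches belong to the nexus Ca2+ hot zone
            out.append(("nexus", f"tuft{a}", 250.0, 1.6, 1.2, "nexus"))
            for b in range(2):
                out.append((f"tuft{a}", f"tuft{a}{b}", 300.0, 1.2, 0.9, "tuft"))
                for c in range(2):
                    out.append((f"tuft{a}{b}", f"tuft{a}{b}{c}", 300.0,
                                0.9, 0.8, "tuft"))
                    for d in range(2):
                        out.append((f"tuft{a}{b}{c}", f"tuft{a}{b}{c}{d}",
                                    t16, 0.8, 0.7, "tuft"))
    return out


def build_synthetic_morphology(params: MorphologyParams | None = None,
                               seed: int | None = None) -> Morphology:
    """Build the deterministic synthetic L5-like morphology.

    At default parameters the apical and basal cable totals equal the
    template targets exactly (7440 and 4649 um); with ``jitter`` > 0 the
    per-section lengths vary (seeded) but subtree totals are renormalized.
    Sections are compartmentalized into segments of at most ``seg_len`` um.

    For reduced cells (scale < 1) dendritic diameters shrink by
    ``diam_scale`` (default sqrt(scale), floored at 0.3 um) so that the
    electrotonic compartmentalization of distal branches is approximately
    preserved while cable lengths scale.
    """
    p = params or MorphologyParams()
    rng = np.random.default_rng(seed)
    dscale = p.diam_scale if p.diam_scale is not None else np.sqrt(p.scale)
    p_scaled = replace(
        p,
        apical_total=p.apical_total * p.scale,
        basal_total=p.basal_total * p.scale,
        trunk_length=p.trunk_length * p.scale,
        oblique_length=p.oblique_length * p.scale,
        nexus_length=max(p.nexus_length * p.scale, 10.0),
        axon_length=p.axon_length,
    )
    sections = [("", "soma", p.soma_length, p.soma_diam, p.soma_diam, "soma"),
                ("soma", "axon", p_scaled.axon_length, p.axon_diam,
                 p.axon_diam, "axon")]
    sections += _basal_sections(p_scaled, rng)
    sections += _apical_sections(p_scaled, rng)
    if dscale != 1.0:
        # thin the terminal subtrees only: the trunk and nexus keep their
        # calibre so the hot zone stays well coupled to the soma
        sections = [
            (s[0], s[1], s[2], max(s[3] * dscale, 0.3),
             max(s[4] * dscale, 0.3), s[5])
            if s[5] in ("basal", "tuft") else s
            for s in sections]

    if p.jitter > 0:
        # jitter dendritic section lengths, then renormalize subtree totals
        sections = [list(s) for s in sections]
        for s in sections:
            if s[5] in ("basal", "apical_trunk", "nexus", "tuft"):
                s[2] *= float(np.exp(rng.normal(0.0, p.jitter)))
        for subtree, target in (("basal", p_scaled.basal_total),
                                ("apical", p_scaled.apical_total)):
            tot = sum(s[2] for s in sections
                      if _SUBTREE[s[5]] == subtree)
            for s in sections:
                if _SUBTREE[s[5]] == subtree:
                    s[2] *= target / tot
        sections = [tuple(s) for s in sections]

    # --- compartmentalize, DFS so parents precede children -----------------
    by_parent: dict[str, list] = {}
    sec_by_name = {}
    for s in sections:
        sec_by_name[s[1]] = s
        by_parent.setdefault(s[0], []).append(s)

    parent, length, diam, region, branch_id = [], [], [], [], []
    xyz = []
    last_comp_of: dict[str, int] = {}
    end_xyz: dict[str, np.ndarray] = {"": np.zeros(3)}
    directions = _section_directions(sections, rng)

    def emit(sec, bid):
        pname, name, L, d0, d1, reg = sec
        n_seg = 1 if reg == "soma" else max(int(np.ceil(L / p.seg_len)), 1)
        seg_l = L / n_seg
        prev = last_comp_of.get(pname, -1)
        start = end_xyz.get(pname, np.zeros(3))
        u = directions[name]
        for k in range(n_seg):
            frac = (k + 0.5) / n_seg
            parent.append(prev)
            length.append(seg_l)
            diam.append(d0 + (d1 - d0) * frac)
            region.append(reg)
            branch_id.append(bid)
            pt = start + u * seg_l * (k + 1)
            xyz.append(pt)
            prev = len(parent) - 1
        last_comp_of[name] = prev
        end_xyz[name] = start + u * L

    bid = 0
    # iterative DFS preserving insertion order
    order: list = []
    def dfs(name):
        for s in by_parent.get(name, []):
            order.append(s)
            dfs(s[1])
    dfs("")
    for s in order:
        emit(s, bid)
        bid += 1
    return Morphology(parent, length, diam, region, branch_id, np.array(xyz))


def _section_directions(sections, rng) -> dict[str, np.ndarray]:
    """Straight-line layout directions: apical up, axon down, basals radial."""
    dirs: dict[str, np.ndarray] = {}
    n_basal = sum(1 for s in sections if s[5] == "basal" and s[0] == "soma")
    b = 0
    for s in sections:
        pname, name, L, d0, d1, reg = s
        if reg == "soma":
            dirs[name] = np.array([0.0, 1.0, 0.0])
        elif reg == "axon":
            dirs[name] = np.array([0.0, -1.0, 0.0])
        elif reg == "basal":
            if pname == "soma":
                ang = 2 * np.pi * b / max(n_basal, 1)
                dirs[name] = np.array([np.cos(ang), -0.6, np.sin(ang)])
                dirs[name] /= np.linalg.norm(dirs[name])
                b += 1
            else:
                base = dirs[pname]
                tilt = rng.normal(0, 0.15, 3) if rng is not None else 0
                v = base + tilt
                dirs[name] = v / np.linalg.norm(v)
        else:  # apical
            if name.startswith("obl"):
                side = 1.0 if int(name[3:]) % 2 == 0 else -1.0
                v = np.array([side, 0.4, 0.0])
                dirs[name] = v / np.linalg.norm(v)
            elif name.startswith("tuft"):
                h = hash(name) % 1000 / 1000.0
                v = np.array([np.cos(2 * np.pi * h), 1.2, np.sin(2 * np.pi * h)])
                dirs[name] = v / np.linalg.norm(v)
            else:
                dirs[name] = np.array([0.0, 1.0, 0.0])
    return dirs
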