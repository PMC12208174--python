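"""Synthetic protein–ligand complexes with planted interface ground truth.

The generator emulates the geometry that the interface-tessellation step
relies on: a folded, helix-like chain whose consecutive CA atoms are spaced
about 3.8 Å apart, one side-chain pseudo-atom per residue, and a small
ligand placed inside a pocket so that

* every residue in ``interface_positions`` has an atom within
  ``0.6 * truncation_radius`` of a ligand atom (first shell),
* every other residue — except the buried decoys — keeps *all* atoms
  farther than ``truncation_radius`` from every ligand atom,
* buried decoys sit within the truncation radius but directly behind a
  first-shell atom on the segment towards their nearest ligand atom, so a
  radially truncated tessellation must exclude them while a plain distance
  cutoff includes them.

Each candidate geometry is verified against these constraints (including a
tessellation check for the decoy occlusion) and rebuilt with fresh jitter on
failure; after a bounded number of retries a :class:`GenerationError` is
raised.  Output is deterministic for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import GenerationError
from .structure_io import Atom, PocketComplex, Residue, ONE_TO_THREE

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    """A generated complex plus its planted ground truth."""

    complex: PocketComplex
    planted_interface: frozenset[int]
    buried_decoys: frozenset[int]
    truncation_radius: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.planted_interface & self.buried_decoys:
            raise ValueError("interface and decoys must be disjoint")
        n = len(self.complex)
        for s in (self.planted_interface, self.buried_decoys):
            if any(i < 0 or i >= n for i in s):
                raise ValueError("planted index out of range")


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis``."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _delaunay_contact_residues(
    prot_xyz: np.ndarray, prot_res: np.ndarray, lig_xyz: np.ndarray, radius: float
) -> set[int]:
    """Residues whose atoms share a Delaunay/Voronoi facet with a ligand
    atom within ``radius`` (same rule as the production tessellation; used
    here only to verify decoy occlusion during generation)."""
    pts = np.vstack([prot_xyz, lig_xyz])
    n_p = len(prot_xyz)
    tri = Delaunay(pts)
    out: set[int] = set()
    for simplex in tri.simplices:
        prot = [i for i in simplex if i < n_p]
        lig = [i for i in simplex if i >= n_p]
        for i in prot:
            for j in lig:
                if np.linalg.norm(pts[i] - pts[j]) <= radius:
                    out.add(int(prot_res[i]))
    return out


def _build_candidate(
    n_residues: int,
    interface: list[int],
    decoys: dict[int, int],
    radius: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One geometry attempt.  Returns (ca_xyz, cb_xyz, lig_xyz)."""
    r = radius
    lig_ray = 0.17 * r          # ligand atoms sit on interface rays
    s_if = 0.45 * r             # interface side-chain radial distance
    ca_if = s_if + 1.8
    d_decoy = r + lig_ray - 0.5
    r_far = 1.2 * r + 0.5       # innermost CA radius of non-pocket residues
    side_len = 1.8
    ca_step = 3.8

    iface_set = set(interface)
    # radial distance per residue
    dist = np.empty(n_residues)
    for i in range(n_residues):
        if i in iface_set:
            dist[i] = ca_if
        elif i in decoys:
            dist[i] = d_decoy
        else:
            dist[i] = r_far + rng.uniform(0.0, 0.8)

    # chain of directions on the unit sphere; step angle chosen so that
    # consecutive CA atoms are ~3.8 A apart where radial jumps permit
    wobble = _unit(rng.normal(size=3))
    u = np.empty((n_residues, 3))
    u[0] = _unit(rng.normal(size=3))
    for i in range(1, n_residues):
        if i in decoys:
            blocker = decoys[i]
            if blocker < i:
                # small angular offset keeps the decoy just off the exact ray
                axis = _unit(np.cross(u[blocker], wobble) + 1e-3 * rng.normal(size=3))
                u[i] = _unit(_rotate(u[blocker], axis, np.deg2rad(3.0)))
                continue
        d0, d1 = dist[i - 1], dist[i]
        cos_t = (d0 * d0 + d1 * d1 - ca_step * ca_step) / (2 * d0 * d1)
        theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
        axis = _unit(np.cross(u[i - 1], wobble) + 0.3 * rng.normal(size=3))
        u[i] = _unit(_rotate(u[i - 1], axis, theta))
    # a decoy placed before its blocker in the chain pins the blocker ray
    for i, blocker in decoys.items():
        if blocker > i:
            axis = _unit(np.cross(u[i], wobble) + 1e-3 * rng.normal(size=3))
            u[blocker] = _unit(_rotate(u[i], axis, np.deg2rad(3.0)))

    jit = lambda scale: rng.normal(scale=scale, size=3)  # noqa: E731
    ca = np.empty((n_residues, 3))
    cb = np.empty((n_residues, 3))
    for i in range(n_residues):
        ca[i] = dist[i] * u[i] + jit(0.05)
        if i in iface_set:
            cb[i] = s_if * u[i] + jit(0.05)      # side chain points into pocket
        else:
            cb[i] = (dist[i] + side_len) * u[i] + jit(0.05)

    # ligand: one atom per interface residue on its ray, padded to >= 3
    lig = [lig_ray * u[q] + jit(0.08) for q in interface]
    while len(lig) < 3:
        lig.append(0.1 * r * _unit(rng.normal(size=3)) * rng.uniform(0.3, 1.0))
    return ca, cb, np.array(lig)


def _check_candidate(
    ca: np.ndarray,
    cb: np.ndarray,
    lig: np.ndarray,
    interface: list[int],
    decoys: dict[int, int],
    radius: float,
) -> bool:
    n = len(ca)
    iface = set(interface)
    atoms = np.stack([ca, cb], axis=1)          # (n, 2, 3)
    d = np.linalg.norm(atoms[:, :, None, :] - lig[None, None, :, :], axis=-1)
    dmin = d.min(axis=(1, 2))                    # per-residue nearest approach
    for i in range(n):
        if i in iface:
            if dmin[i] > 0.6 * radius - 1e-9:
                return False
        elif i in decoys:
            if not (dmin[i] <= radius - 0.2):
                return False
        else:
            if dmin[i] <= radius + 0.2:          # margin for rigid-motion tests
                return False
    # occlusion: tessellation contacts must be exactly the planted interface
    prot_xyz = atoms.reshape(-1, 3)
    prot_res = np.repeat(np.arange(n), 2)
    try:
        found = _delaunay_contact_residues(prot_xyz, prot_res, lig, radius)
    except QhullError:
        return False
    return found == iface


def generate_synthetic_complex(
    n_residues: int,
    interface_positions: set[int] | frozenset[int] | list[int],
    truncation_radius: float = 6.0,
    seed: int = 0,
    n_decoys: int = 2,
    max_retries: int = 40,
    complex_id: str | None = None,
) -> SyntheticTruth:
    """Build a synthetic complex with a planted interface.

    Raises
    ------
    ValueError
        If preconditions are violated (``n_residues < 8``, out-of-range
        interface positions, non-positive radius).
    GenerationError
        If no geometry satisfying all distance and occlusion constraints is
        found within ``max_retries`` attempts.
    """
    if n_residues < 8:
        raise ValueError("n_residues must be >= 8")
    if truncation_radius <= 0:
        raise ValueError("truncation_radius must be > 0")
    interface = sorted(int(i) for i in interface_positions)
    if not interface:
        raise ValueError("interface_positions must be non-empty")
    if interface[0] < 0 or interface[-1] >= n_residues:
        raise ValueError("interface_positions out of range")
    if len(interface) > 8:
        raise GenerationError(
            "at most 8 planted interface residues are supported (one ligand "
            "atom per first-shell residue, ligand capped at 8 heavy atoms)"
        )

    iface_set = set(interface)
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, attempt])
        # decoys hide directly behind a chain neighbour of an interface residue
        candidates = [
            q + 1 for q in interface
            if q + 1 < n_residues and q + 1 not in iface_set
        ]
        decoy_list = candidates[: max(0, n_decoys)]
        decoys = {p: p - 1 for p in decoy_list}

        ca, cb, lig = _build_candidate(
            n_residues, interface, decoys, truncation_radius, rng
        )
        if not _check_candidate(ca, cb, lig, interface, decoys, truncation_radius):
            continue

        names = rng.choice(list(_AA20), size=n_residues)
        residues = [
            Residue(
                "A",
                i,
                ONE_TO_THREE[names[i]],
                [
                    Atom("C", ca[i], "CA", is_backbone=True),
                    Atom("C", cb[i], "CB"),
                ],
            )
            for i in range(n_residues)
        ]
        ligand_atoms = [
            Atom("C", lig[k], f"C{k + 1}") for k in range(len(lig))
        ]
        cid = complex_id or f"synthetic_s{seed}"
        cplx = PocketComplex(
            complex_id=cid,
            residues=residues,
            ligand_atoms=ligand_atoms,
            author_lookup={("A", i + 1, ""): i for i in range(n_residues)},
            ligand_name="LIG",
        )
        return SyntheticTruth(
            complex=cplx,
            planted_interface=frozenset(iface_set),
            buried_decoys=frozenset(decoys),
            truncation_radius=truncation_radius,
            meta={"seed": seed, "attempt": attempt},
        )
    raise GenerationError(
        f"no admissible geometry after {max_retries} attempts "
        f"(n={n_residues}, interface={interface}, r={truncation_radius})"
    )


# --------------------------------------------------------------------------
# Families of related pockets
# --------------------------------------------------------------------------

@dataclass
class FamilyMember:
    truth: SyntheticTruth
    family: int
    superfamily: int


def _mutate_sequence(
    truth: SyntheticTruth,
    positions: list[int],
    rng: np.random.Generator,
    member_id: str,
) -> SyntheticTruth:
    residues = []
    pos_set = set(positions)
    for r in truth.complex.residues:
        name = r.res_name
        if r.seq_index in pos_set:
            current = r.one_letter
            choices = [a for a in _AA20 if a != current]
            name = ONE_TO_THREE[str(rng.choice(choices))]
        residues.append(Residue(r.chain_id, r.seq_index, name, r.atoms))
    cplx = PocketComplex(
        complex_id=member_id,
        residues=residues,
        ligand_atoms=truth.complex.ligand_atoms,
        author_lookup=dict(truth.complex.author_lookup),
        ligand_name=truth.complex.ligand_name,
    )
    return SyntheticTruth(
        complex=cplx,
        planted_interface=truth.planted_interface,
        buried_decoys=truth.buried_decoys,
        truncation_radius=truth.truncation_radius,
        meta=dict(truth.meta),
    )


def _spaced_positions(
    n_residues: int, k: int, rng: np.random.Generator, min_gap: int = 3
) -> list[int]:
    """k positions in [1, n-2] with pairwise gaps >= min_gap (leaves room
    for the chain-neighbour decoys)."""
    for _ in range(2000):
        cand = sorted(rng.choice(np.arange(1, n_residues - 1), size=k, replace=False))
        if all(b - a >= min_gap for a, b in zip(cand, cand[1:])):
            return [int(x) for x in cand]
    raise GenerationError("could not place interface positions with spacing")


def generate_pocket_families(
    n_superfamilies: int = 2,
    families_per_superfamily: int = 3,
    members_per_family: int = 10,
    n_residues: int = 48,
    n_interface: int = 8,
    truncation_radius: float = 6.0,
    seed: int = 0,
    interface_overlap: float = 0.375,
    member_interface_mutation_prob: float = 0.7,
    member_other_mutations: int = 2,
) -> list[FamilyMember]:
    """Generate a two-level hierarchy of related pockets.

    Each *superfamily* starts from an ancestral sequence and interface
    position set.  Families within a superfamily inherit the ancestor with
    a fraction ``1 - interface_overlap`` of interface positions relocated
    and ~8% of sequence positions mutated; each family gets its own folded
    geometry.  Members of a family share that geometry and differ only by
    point mutations: one designated *hypervariable* interface site (mutated
    with probability ``member_interface_mutation_prob``) plus a couple of
    non-interface mutations.  Any within-family pocket pair therefore
    differs at no more than one pooled interface row, while sibling
    families differ at the relocated interface positions — small
    within-family embedding distances, intermediate distances between
    sibling families, and large distances across superfamilies: the
    cluster/branch structure that the atlas, split, and hardness analyses
    operate on.
    """
    master = np.random.default_rng(seed & 0x7FFFFFFF)
    out: list[FamilyMember] = []
    fam_id = 0
    for s in range(n_superfamilies):
        anc_rng = np.random.default_rng(master.integers(2**31))
        anc_positions = _spaced_positions(n_residues, n_interface, anc_rng)
        for f in range(families_per_superfamily):
            fam_rng = np.random.default_rng(master.integers(2**31))
            n_keep = int(round(interface_overlap * n_interface))
            keep = list(fam_rng.choice(anc_positions, size=n_keep, replace=False))
            # relocate the remaining interface positions, keeping spacing
            positions = [int(x) for x in keep]
            guard = 0
            while len(positions) < n_interface and guard < 500:
                guard += 1
                p = int(fam_rng.integers(1, n_residues - 1))
                if all(abs(p - q) >= 3 for q in positions):
                    positions.append(p)
            if len(positions) < n_interface:
                raise GenerationError("family interface placement failed")
            truth = generate_synthetic_complex(
                n_residues,
                set(positions),
                truncation_radius,
                seed=int(fam_rng.integers(2**31)),
                complex_id=f"sf{s}_f{fam_id}_m0",
            )
            # all families of a superfamily share an ancestral sequence
            truth = _apply_ancestor_sequence(truth, s, seed, fam_rng)
            hypervariable = int(fam_rng.choice(sorted(truth.planted_interface)))
            for m in range(members_per_family):
                mem_rng = np.random.default_rng(master.integers(2**31))
                if m == 0:
                    member = _relabel(truth, f"sf{s}_f{fam_id}_m0")
                else:
                    others = [
                        i for i in range(n_residues)
                        if i not in truth.planted_interface
                    ]
                    targets = [
                        int(t) for t in mem_rng.choice(
                            others,
                            size=min(member_other_mutations, len(others)),
                            replace=False,
                        )
                    ]
                    if mem_rng.random() < member_interface_mutation_prob:
                        targets.append(hypervariable)
                    member = _mutate_sequence(
                        truth, targets, mem_rng, f"sf{s}_f{fam_id}_m{m}",
                    )
                out.append(FamilyMember(member, family=fam_id, superfamily=s))
            fam_id += 1
    return out


def _relabel(truth: SyntheticTruth, new_id: str) -> SyntheticTruth:
    cplx = PocketComplex(
        complex_id=new_id,
        residues=truth.complex.residues,
        ligand_atoms=truth.complex.ligand_atoms,
        author_lookup=dict(truth.complex.author_lookup),
        ligand_name=truth.complex.ligand_name,
    )
    return SyntheticTruth(
        complex=cplx,
        planted_interface=truth.planted_interface,
        buried_decoys=truth.buried_decoys,
        truncation_radius=truth.truncation_radius,
        meta=dict(truth.meta),
    )


def _apply_ancestor_sequence(
    truth: SyntheticTruth, superfamily: int, seed: int, fam_rng: np.random.Generator
) -> SyntheticTruth:
    """Give all families of a superfamily a shared ancestral sequence
    (deterministic in (seed, superfamily)), then apply ~8% family-level
    divergence."""
    n = len(truth.complex)
    anc = np.random.default_rng([seed & 0x7FFFFFFF, 7919, superfamily])
    letters = anc.choice(list(_AA20), size=n)
    residues = [
        Residue(r.chain_id, r.seq_index, ONE_TO_THREE[str(letters[r.seq_index])], r.atoms)
        for r in truth.complex.residues
    ]
    cplx = PocketComplex(
        complex_id=truth.complex.complex_id,
        residues=residues,
        ligand_atoms=truth.complex.ligand_atoms,
        author_lookup=dict(truth.complex.author_lookup),
        ligand_name=truth.complex.ligand_name,
    )
    base = SyntheticTruth(
        complex=cplx,
        planted_interface=truth.planted_interface,
        buried_decoys=truth.buried_decoys,
        truncation_radius=truth.truncation_radius,
        meta=dict(truth.meta),
    )
    n_div = max(1, int(round(0.08 * n)))
    targets = [int(t) for t in fam_rng.choice(n, size=n_div, replace=False)]
    return _mutate_sequence(base, targets, fam_rng, cplx.complex_id)
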