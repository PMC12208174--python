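"""Protein–ligand complex parsing, selection, and serialization.

A :class:`PocketComplex` holds the heavy atoms of one protein (grouped into
residues in chain order) together with the heavy atoms of a single selected
ligand (HET group).  Residues are indexed by 0-based *sequence position*
within the extracted chain concatenation — not by PDB author numbering —
because per-residue language-model embeddings are addressed by sequence
position.  A lookup table ``(chain, author number, insertion code) ->
seq_index`` is retained so structure and sequence stay aligned.

PDB is the only structure format supported; parsing and writing go through
:mod:`gemmi`.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    AmbiguousLigand,
    EmptyProtein,
    LigandNotFound,
    ParseError,
)

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: HET groups that are never selectable as the probe ligand: waters plus
#: common crystallization buffers, cryoprotectants and salts.  Configurable
#: via the ``exclude`` argument of :func:`read_complex`.
DEFAULT_LIGAND_EXCLUDE = WATER_NAMES | frozenset(
    {"GOL", "EDO", "PEG", "PGE", "DMS", "ACT", "FMT", "MPD",
     "SO4", "PO4", "NO3", "CIT", "TRS", "MES", "EPE",
     "NA", "CL", "K", "BR", "IOD", "CS", "LI"}
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is deposited as HETATM but is a polymer residue
    "MSE": "M",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}


@dataclass
class Atom:
    """One heavy atom: element symbol, Cartesian coordinates in Å, the PDB
    atom name, and whether it is a backbone atom (N/CA/C/O of a standard
    residue)."""

    element: str
    coords: np.ndarray
    atom_name: str
    is_backbone: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError("element symbol must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_index: int
    res_name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.seq_index < 0:
            raise ValueError("seq_index must be >= 0")
        if not self.atoms:
            raise ValueError("residue must hold at least one atom")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class PocketComplex:
    """One protein chain (or chain concatenation) plus one ligand's heavy
    atoms.  ``sequence`` is derived from the residues; nonstandard protein
    residues map to ``'X'`` and are listed in ``parse_report``."""

    complex_id: str
    residues: list[Residue]
    ligand_atoms: list[Atom]
    author_lookup: dict[tuple[str, int, str], int] = field(default_factory=dict)
    ligand_name: str = "LIG"
    parse_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError("ligand_atoms must be non-empty")
        idx = [r.seq_index for r in self.residues]
        if idx != list(range(len(idx))):
            raise ValueError("residues must carry consecutive 0-based seq_index")

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def protein_coords(self) -> np.ndarray:
        """All protein heavy-atom coordinates, residue-major order."""
        return np.concatenate([r.coords() for r in self.residues])

    def atom_residue_index(self) -> np.ndarray:
        """Residue seq_index of each row of :meth:`protein_coords`."""
        return np.concatenate(
            [np.full(len(r.atoms), r.seq_index, dtype=int) for r in self.residues]
        )

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms])

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def atom_d(a: Atom) -> dict:
            return {
                "element": a.element,
                "coords": [round(float(x), 5) for x in a.coords],
                "name": a.atom_name,
                "backbone": a.is_backbone,
            }

        return {
            "complex_id": self.complex_id,
            "ligand_name": self.ligand_name,
            "residues": [
                {
                    "chain": r.chain_id,
                    "seq_index": r.seq_index,
                    "res_name": r.res_name,
                    "atoms": [atom_d(a) for a in r.atoms],
                }
                for r in self.residues
            ],
            "ligand_atoms": [atom_d(a) for a in self.ligand_atoms],
            "author_lookup": [
                [list(k), v] for k, v in self.author_lookup.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PocketComplex":
        def atom_o(ad: dict) -> Atom:
            return Atom(ad["element"], np.array(ad["coords"], dtype=float),
                        ad["name"], ad.get("backbone", False))

        residues = [
            Residue(rd["chain"], rd["seq_index"], rd["res_name"],
                    [atom_o(ad) for ad in rd["atoms"]])
            for rd in d["residues"]
        ]
        lookup = {tuple(k): v for k, v in d.get("author_lookup", [])}
        return cls(
            complex_id=d["complex_id"],
            residues=residues,
            ligand_atoms=[atom_o(ad) for ad in d["ligand_atoms"]],
            author_lookup=lookup,
            ligand_name=d.get("ligand_name", "LIG"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PocketComplex":
        return cls.from_dict(json.loads(text))


# --------------------------------------------------------------------------
# PDB reading
# --------------------------------------------------------------------------

def _read_structure(pdb_source) -> gemmi.Structure:
    try:
        if isinstance(pdb_source, Path) or (
            isinstance(pdb_source, str)
            and "\n" not in pdb_source
            and os.path.exists(pdb_source)
        ):
            st = gemmi.read_structure(str(pdb_source), format=gemmi.CoorFormat.Pdb)
        else:
            st = gemmi.read_pdb_string(str(pdb_source))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse PDB input: {exc}") from exc
    if len(st) == 0:
        raise ParseError("PDB input holds no model")
    n_atoms = sum(len(res) for chain in st[0] for res in chain)
    if n_atoms == 0:
        raise ParseError("no ATOM/HETATM records found")
    return st


def _altloc(atom: gemmi.Atom) -> str:
    al = atom.altloc
    return "" if al in ("", "\x00") else al


def _resolve_altlocs(res: gemmi.Residue, keep_hydrogens: bool) -> list[gemmi.Atom]:
    """One atom per atom name: highest occupancy wins, ties prefer altloc
    'A', then lexicographic order."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.is_hydrogen() and not keep_hydrogens:
            continue
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
            continue
        key = (-atom.occ, _altloc(atom) != "A", _altloc(atom))
        prev_key = (-prev.occ, _altloc(prev) != "A", _altloc(prev))
        if key < prev_key:
            chosen[atom.name] = atom
    return list(chosen.values())


def _is_water(name: str) -> bool:
    return name in WATER_NAMES


def _iter_het_groups(model: gemmi.Model):
    """Yield (chain_id, residue) for every non-water HETATM group that is
    not a polymer residue."""
    for chain in model:
        for res in chain:
            if res.het_flag != "H":
                continue
            if _is_water(res.name) or res.name in THREE_TO_ONE:
                continue
            yield chain.name, res


def list_ligands(pdb_source) -> list[tuple[str, str, int, int]]:
    """All non-water HETATM groups as ``(het_code, chain, residue_number,
    heavy_atom_count)``, ordered by (chain, residue number)."""
    st = _read_structure(pdb_source)
    out = []
    for chain_id, res in _iter_het_groups(st[0]):
        n_heavy = sum(1 for a in res if not a.is_hydrogen())
        out.append((res.name, chain_id, res.seqid.num, n_heavy))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def _parse_selector(selector: str) -> tuple[str, str | None, int | None]:
    parts = selector.split(":")
    code = parts[0]
    chain = parts[1] if len(parts) > 1 and parts[1] else None
    resnum = int(parts[2]) if len(parts) > 2 and parts[2] else None
    return code, chain, resnum


def read_complex(
    pdb_source,
    ligand_selector: str,
    chain_filter: Sequence[str] | None = None,
    keep_hydrogens: bool = False,
    multi_chain: bool = False,
    exclude: Iterable[str] = DEFAULT_LIGAND_EXCLUDE,
    complex_id: str | None = None,
) -> PocketComplex:
    """Parse a protein–ligand complex from PDB text or a PDB file.

    Parameters
    ----------
    ligand_selector:
        ``"CODE"``, ``"CODE:CHAIN"`` or ``"CODE:CHAIN:RESNUM"``.  Waters and
        the configurable buffer list are never selectable.
    chain_filter:
        If given, only these protein chains are extracted.  Otherwise the
        single chain with the most ligand contacts is used, or — with
        ``multi_chain=True`` — all chains with an atom within 10 Å of the
        ligand, concatenated in chain-id order.
    """
    st = _read_structure(pdb_source)
    model = st[0]
    exclude = frozenset(exclude)

    code, sel_chain, sel_num = _parse_selector(ligand_selector)
    candidates = []
    for chain_id, res in _iter_het_groups(model):
        if res.name != code:
            continue
        if sel_chain is not None and chain_id != sel_chain:
            continue
        if sel_num is not None and res.seqid.num != sel_num:
            continue
        candidates.append((chain_id, res))
    if not candidates:
        raise LigandNotFound(
            f"no selectable HETATM group matches {ligand_selector!r}"
            + (" (waters/buffers are excluded)" if code in exclude or _is_water(code) else "")
        )
    if code in exclude:
        raise LigandNotFound(f"{code!r} is on the probe-ligand exclusion list")
    if len(candidates) > 1:
        raise AmbiguousLigand(
            f"{ligand_selector!r} matches {len(candidates)} HETATM groups; "
            "disambiguate with CODE:CHAIN or CODE:CHAIN:RESNUM"
        )
    lig_chain, lig_res = candidates[0]
    ligand_atoms = [
        Atom(a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]), a.name)
        for a in _resolve_altlocs(lig_res, keep_hydrogens)
    ]
    if not ligand_atoms:
        raise LigandNotFound(f"{ligand_selector!r} has no heavy atoms")
    lig_xyz = np.array([a.coords for a in ligand_atoms])

    # collect protein residues per chain, in file order
    per_chain: dict[str, list[tuple[gemmi.Residue, list[gemmi.Atom]]]] = {}
    nonstandard: list[str] = []
    for chain in model:
        kept = []
        for res in chain:
            is_protein = res.het_flag == "A" or (
                res.het_flag == "H" and res.name in THREE_TO_ONE
            )
            if not is_protein:
                continue
            atoms = _resolve_altlocs(res, keep_hydrogens)
            if not atoms:
                continue
            if res.name not in THREE_TO_ONE:
                nonstandard.append(f"{chain.name}/{res.name}{res.seqid.num}")
            kept.append((res, atoms))
        if kept:
            per_chain.setdefault(chain.name, []).extend(kept)

    if chain_filter is not None:
        selected = [c for c in sorted(per_chain) if c in set(chain_filter)]
    elif per_chain:
        def contacts(cid: str) -> int:
            xyz = np.array(
                [[a.pos.x, a.pos.y, a.pos.z]
                 for _, atoms in per_chain[cid] for a in atoms]
            )
            d = np.linalg.norm(xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
            return int((d <= 4.5).sum())

        if multi_chain:
            def near(cid: str) -> bool:
                xyz = np.array(
                    [[a.pos.x, a.pos.y, a.pos.z]
                     for _, atoms in per_chain[cid] for a in atoms]
                )
                d = np.linalg.norm(xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
                return bool((d <= 10.0).any())

            selected = [c for c in sorted(per_chain) if near(c)]
            if not selected:
                selected = sorted(per_chain)
        else:
            ranked = sorted(per_chain, key=lambda c: (-contacts(c), c))
            selected = [ranked[0]]
    else:
        selected = []

    residues: list[Residue] = []
    lookup: dict[tuple[str, int, str], int] = {}
    for cid in selected:
        for gres, atoms in per_chain[cid]:
            std = gres.name in THREE_TO_ONE
            ratoms = [
                Atom(
                    a.element.name,
                    np.array([a.pos.x, a.pos.y, a.pos.z]),
                    a.name,
                    is_backbone=std and a.name in BACKBONE_ATOM_NAMES,
                )
                for a in atoms
            ]
            idx = len(residues)
            icode = gres.seqid.icode.strip()
            lookup[(cid, gres.seqid.num, icode)] = idx
            residues.append(Residue(cid, idx, gres.name, ratoms))

    if not residues:
        raise EmptyProtein("no protein residues remain after filtering")

    if complex_id is None:
        complex_id = f"{st.name or 'complex'}_{code}_{lig_chain}{lig_res.seqid.num}"
    return PocketComplex(
        complex_id=complex_id,
        residues=residues,
        ligand_atoms=ligand_atoms,
        author_lookup=lookup,
        ligand_name=code,
        parse_report={"nonstandard_residues": nonstandard,
                      "chains": selected},
    )


# --------------------------------------------------------------------------
# PDB writing (round trip)
# --------------------------------------------------------------------------

def write_pdb(cplx: PocketComplex) -> str:
    """Render a :class:`PocketComplex` as PDB text.  Reading the text back
    with :func:`read_complex` reproduces residues, sequence, and ligand
    atoms with coordinates at the PDB 3-decimal convention."""
    st = gemmi.Structure()
    st.name = cplx.complex_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    inv_lookup = {v: k for k, v in cplx.author_lookup.items()}

    def make_atom(a: Atom) -> gemmi.Atom:
        g = gemmi.Atom()
        g.name = a.atom_name
        g.element = gemmi.Element(a.element)
        g.pos = gemmi.Position(*a.coords)
        g.occ = 1.0
        return g

    for r in cplx.residues:
        ch = chains.get(r.chain_id)
        if ch is None:
            ch = gemmi.Chain(r.chain_id)
            chains[r.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = r.res_name
        auth = inv_lookup.get(r.seq_index)
        num = auth[1] if auth else r.seq_index + 1
        icode = auth[2] if auth and auth[2] else " "
        gres.seqid = gemmi.SeqId(num, icode)
        gres.het_flag = "A"
        for a in r.atoms:
            gres.add_atom(make_atom(a))
        ch.add_residue(gres)

    lig_chain_id = "Z" if "Z" not in chains else "z"
    lch = gemmi.Chain(lig_chain_id)
    lres = gemmi.Residue()
    lres.name = cplx.ligand_name
    lres.seqid = gemmi.SeqId(900, " ")
    lres.het_flag = "H"
    for a in cplx.ligand_atoms:
        lres.add_atom(make_atom(a))
    lch.add_residue(lres)

    for ch in chains.values():
        model.add_chain(ch)
    model.add_chain(lch)
    st.add_model(model)
    return st.make_pdb_string()
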