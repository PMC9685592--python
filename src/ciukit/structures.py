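"""Protein structure and trajectory I/O, and ionizable-site bookkeeping.

Structures are flat atom lists — element, coordinates in Å, atom/residue
naming — with one :class:`Structure` per trajectory frame.  Protonation is
bookkeeping on :class:`IonizableSite` objects (one representative anchor atom
per site), never explicit hydrogens, so structures without hydrogens are
handled everywhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from ciukit.errors import (
    ConfigMismatchError,
    EmptyInputError,
    MissingAnchorError,
    ParseError,
)

__all__ = [
    "Atom",
    "Structure",
    "SiteKind",
    "IonizableSite",
    "read_structure",
    "write_structure",
    "read_xyz",
    "find_ionizable_sites",
    "write_protonation_states",
    "read_protonation_states",
]


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    Coordinates are in Å.  ``res_seq`` keeps the deposited (1-based) residue
    number; insertion codes are carried separately and appended when a string
    key is needed.
    """

    element: str
    name: str
    x: float
    y: float
    z: float
    res_name: str
    res_seq: int
    chain_id: str = "A"
    icode: str = ""

    @property
    def res_key(self) -> str:
        return f"{self.res_seq}{self.icode}"

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """An atom list for one conformer or trajectory frame."""

    atoms: list[Atom]
    frame_id: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyInputError("structure has zero atoms")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite atom coordinate")
        for chain_id, residues in self._residues_by_chain().items():
            seqs = [r[0] for r in residues]
            if any(b < a for a, b in zip(seqs, seqs[1:])):
                raise ValueError(
                    f"residue numbers decrease within chain {chain_id!r}"
                )

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def _residues_by_chain(self) -> dict[str, list[tuple[int, str, str]]]:
        """Ordered unique residues per chain as (res_seq, icode, res_name)."""
        out: dict[str, list[tuple[int, str, str]]] = {}
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.icode)
            if key not in seen:
                seen.add(key)
                out.setdefault(a.chain_id, []).append(
                    (a.res_seq, a.icode, a.res_name)
                )
        return out

    @property
    def residues(self) -> list[tuple[str, int, str, str]]:
        """All residues in order as (chain_id, res_seq, icode, res_name)."""
        return [
            (ch, rs, ic, rn)
            for ch, rr in self._residues_by_chain().items()
            for rs, ic, rn in rr
        ]

    @property
    def sequence(self) -> str:
        """One-letter residue string derived from the residue records."""
        return "".join(
            seq1(rn, undef_code="X") for _, _, _, rn in self.residues
        )

    def translated(self, shift: np.ndarray) -> "Structure":
        shift = np.asarray(shift, dtype=float)
        return Structure(
            [
                replace(a, x=a.x + shift[0], y=a.y + shift[1], z=a.z + shift[2])
                for a in self.atoms
            ],
            frame_id=self.frame_id,
        )

    def rotated(self, rotation: np.ndarray) -> "Structure":
        R = np.asarray(rotation, dtype=float)
        new = self.coords @ R.T
        return Structure(
            [
                replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
                for a, p in zip(self.atoms, new)
            ],
            frame_id=self.frame_id,
        )


class SiteKind(str, Enum):
    """Kinds of ionizable site; basic kinds carry +1 when protonated,
    acidic kinds carry −1 when deprotonated."""

    NTERM = "NTERM"
    CTERM = "CTERM"
    LYS = "LYS"
    ARG = "ARG"
    HIS = "HIS"
    ASP = "ASP"
    GLU = "GLU"


BASIC_KINDS = frozenset({SiteKind.NTERM, SiteKind.LYS, SiteKind.ARG, SiteKind.HIS})
ACIDIC_KINDS = frozenset({SiteKind.CTERM, SiteKind.ASP, SiteKind.GLU})

# One representative point-charge anchor per side-chain site.
SIDECHAIN_ANCHORS = {
    "LYS": (SiteKind.LYS, "NZ"),
    "ARG": (SiteKind.ARG, "CZ"),
    "HIS": (SiteKind.HIS, "NE2"),
    "ASP": (SiteKind.ASP, "CG"),
    "GLU": (SiteKind.GLU, "CD"),
}


@dataclass(frozen=True)
class IonizableSite:
    """A protonatable/deprotonatable location anchored on one atom."""

    site_id: int
    kind: SiteKind
    res_seq: int
    chain_id: str
    anchor_atom: int
    icode: str = ""

    @property
    def is_basic(self) -> bool:
        return self.kind in BASIC_KINDS

    @property
    def res_key(self) -> str:
        return f"{self.res_seq}{self.icode}"


def _prescan_pdb(pdb_text: str) -> None:
    """Raise ParseError naming the line for malformed ATOM/HETATM records."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError(f"truncated ATOM record at line {lineno}")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise ParseError(
                f"malformed ATOM record at line {lineno}: {exc}"
            ) from None


_ELEMENT_FROM_NAME = {"C": "C", "N": "N", "O": "O", "S": "S", "H": "H", "P": "P"}


def read_structure(pdb_text: str) -> list[Structure]:
    """Parse PDB text into one :class:`Structure` per MODEL.

    A file without MODEL records yields exactly one frame.  For disordered
    atoms the highest-occupancy altloc is kept (Biopython's selection rule).
    """
    _prescan_pdb(pdb_text)
    if not any(line.startswith(("ATOM", "HETATM")) for line in pdb_text.splitlines()):
        raise EmptyInputError("no ATOM/HETATM records in PDB input")
    parser = PDBParser(QUIET=True)
    bio = parser.get_structure("frames", io.StringIO(pdb_text))
    frames: list[Structure] = []
    for model in bio:
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                _, res_seq, icode = res.id
                for atom in res:
                    element = (atom.element or "").strip().capitalize()
                    if not element:
                        element = _ELEMENT_FROM_NAME.get(
                            atom.get_name().lstrip("0123456789")[:1], "C"
                        )
                    x, y, z = map(float, atom.coord)
                    atoms.append(
                        Atom(
                            element=element,
                            name=atom.get_name(),
                            x=x,
                            y=y,
                            z=z,
                            res_name=res.get_resname().strip(),
                            res_seq=int(res_seq),
                            chain_id=str(chain.id).strip() or "A",
                            icode=icode.strip(),
                        )
                    )
        if atoms:
            frames.append(Structure(atoms, frame_id=len(frames)))
    if not frames:
        raise EmptyInputError("no frames with atoms in PDB input")
    return frames


def _format_atom_line(serial: int, a: Atom) -> str:
    name = a.name
    if len(name) < 4 and len(a.element) == 1:
        name = f" {name}"
    return (
        f"ATOM  {serial:5d} {name:<4s} {a.res_name:<3s} {a.chain_id[:1]:1s}"
        f"{a.res_seq:4d}{a.icode[:1]:1s}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}  1.00  0.00          {a.element:>2s}"
    )


def write_structure(frames: Structure | list[Structure]) -> str:
    """Emit PDB text; multi-frame input becomes MODEL/ENDMDL blocks."""
    if isinstance(frames, Structure):
        frames = [frames]
    if not frames:
        raise EmptyInputError("no frames to write")
    lines: list[str] = []
    multi = len(frames) > 1
    for i, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL {i:8d}")
        for serial, a in enumerate(frame.atoms, start=1):
            lines.append(_format_atom_line(serial, a))
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_xyz(xyz_text: str) -> list[Structure]:
    """Read multi-frame XYZ text (element + Cartesian Å per line).

    XYZ carries no residue topology, so every atom lands in residue UNK 1.
    """
    lines = xyz_text.splitlines()
    frames: list[Structure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count at line {i + 1}") from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(f"frame starting at line {i + 1} is truncated")
        atoms = []
        for j, rec in enumerate(block):
            parts = rec.split()
            if len(parts) < 4:
                raise ParseError(f"malformed XYZ record at line {i + 3 + j}")
            atoms.append(
                Atom(
                    element=parts[0].capitalize(),
                    name=parts[0].upper(),
                    x=float(parts[1]),
                    y=float(parts[2]),
                    z=float(parts[3]),
                    res_name="UNK",
                    res_seq=1,
                )
            )
        frames.append(Structure(atoms, frame_id=len(frames)))
        i += 2 + n
    if not frames:
        raise EmptyInputError("no frames in XYZ input")
    return frames


_KIND_RANK = {k: 1 for k in SiteKind}
_KIND_RANK[SiteKind.NTERM] = 0
_KIND_RANK[SiteKind.CTERM] = 2


def find_ionizable_sites(s: Structure) -> list[IonizableSite]:
    """Locate every ionizable site: one per K/R/H/D/E residue plus the two
    termini of each chain.

    Ordering is deterministic — by chain, residue number, then kind (N-terminus
    before a side-chain site on the same residue, C-terminus after) — and does
    not depend on atom record order.
    """
    by_chain = s._residues_by_chain()
    # index atoms by (chain, res_seq, icode, atom name) for anchor lookup
    atom_index: dict[tuple[str, int, str, str], int] = {}
    for idx, a in enumerate(s.atoms):
        atom_index.setdefault((a.chain_id, a.res_seq, a.icode, a.name), idx)

    def anchor(chain: str, rs: int, ic: str, name: str, label: str) -> int:
        key = (chain, rs, ic, name)
        if key not in atom_index:
            raise MissingAnchorError(
                f"residue {label} {rs}{ic} chain {chain!r} lacks anchor atom {name}"
            )
        return atom_index[key]

    raw: list[tuple[str, int, str, int, SiteKind, int]] = []
    for chain_id, residues in by_chain.items():
        first_rs, first_ic, first_rn = residues[0]
        last_rs, last_ic, last_rn = residues[-1]
        raw.append(
            (chain_id, first_rs, first_ic, _KIND_RANK[SiteKind.NTERM],
             SiteKind.NTERM, anchor(chain_id, first_rs, first_ic, "N", first_rn))
        )
        raw.append(
            (chain_id, last_rs, last_ic, _KIND_RANK[SiteKind.CTERM],
             SiteKind.CTERM, anchor(chain_id, last_rs, last_ic, "C", last_rn))
        )
        for rs, ic, rn in residues:
            if rn in SIDECHAIN_ANCHORS:
                kind, atom_name = SIDECHAIN_ANCHORS[rn]
                raw.append(
                    (chain_id, rs, ic, _KIND_RANK[kind], kind,
                     anchor(chain_id, rs, ic, atom_name, rn))
                )
    raw.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return [
        IonizableSite(
            site_id=i, kind=kind, res_seq=rs, chain_id=ch,
            anchor_atom=aidx, icode=ic,
        )
        for i, (ch, rs, ic, _, kind, aidx) in enumerate(raw)
    ]


def write_protonation_states(sites: list[IonizableSite], cfg) -> str:
    """Serialize a charge configuration as an engine-agnostic text record.

    One line per site — site id, kind, residue key, chain, protonated flag —
    preceded by the net charge.  Round-trips losslessly through
    :func:`read_protonation_states`.
    """
    states = tuple(cfg.states)
    if len(states) != len(sites):
        raise ConfigMismatchError(
            f"configuration has {len(states)} states for {len(sites)} sites"
        )
    lines = [f"# net_charge {cfg.z}"]
    for site, prot in zip(sites, states):
        lines.append(
            f"{site.site_id}\t{site.kind.value}\t{site.res_key}\t"
            f"{site.chain_id}\t{'protonated' if prot else 'deprotonated'}"
        )
    return "\n".join(lines) + "\n"


def read_protonation_states(text: str):
    """Parse the record written by :func:`write_protonation_states`."""
    from ciukit.mobile_proton import ChargeConfiguration

    z = None
    entries: list[tuple[int, bool]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "net_charge":
                z = int(parts[1])
            continue
        parts = line.split("\t")
        if len(parts) != 5 or parts[4] not in ("protonated", "deprotonated"):
            raise ParseError(f"malformed protonation record at line {lineno}")
        entries.append((int(parts[0]), parts[4] == "protonated"))
    if z is None or not entries:
        raise ParseError("protonation record missing header or sites")
    entries.sort(key=lambda t: t[0])
    return ChargeConfiguration(
        states=tuple(p for _, p in entries), z=z, energy=None
    )
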