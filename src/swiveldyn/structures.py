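"""Structure reading, residue-number mapping and ensemble assembly.

The canonical residue frame is mature *Flaveria trinervia* PPDK numbering
(post transit-peptide cleavage, 1-based): every landmark residue used in the
geometry module (H456, H565, S215, E272) is addressed in this frame.
Structures from other organisms are brought into it with a
:class:`ResidueMap` before any cross-structure analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residue names treated as solvent and excluded on reading
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: residue key = (residue number, insertion code); '' when no insertion code
ResKey = tuple[int, str]


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float
    is_hetero: bool

    @property
    def reskey(self) -> ResKey:
        return (self.resnum, self.icode)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class StructureModel:
    """Labeled atomic coordinates of one chain of one model."""

    id: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not np.all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates for atom {a}")

    # -- selection helpers -------------------------------------------------

    def polymer_residues(self) -> list[ResKey]:
        """Ordered unique residue keys of polymer (non-hetero) residues."""
        seen: dict[ResKey, None] = {}
        for a in self.atoms:
            if not a.is_hetero:
                seen.setdefault(a.reskey, None)
        return list(seen)

    def ca_residues(self) -> list[ResKey]:
        """Residue keys of polymer residues possessing a C-alpha atom."""
        seen: dict[ResKey, None] = {}
        for a in self.atoms:
            if not a.is_hetero and a.name == "CA":
                seen.setdefault(a.reskey, None)
        return list(seen)

    def get_atom(self, resnum: int, atom_name: str, icode: str = "",
                 hetero: bool | None = None) -> Atom:
        """Return one atom; raise with nearest available names if absent."""
        names = []
        for a in self.atoms:
            if a.resnum == resnum and a.icode == icode and (
                    hetero is None or a.is_hetero == hetero):
                if a.name == atom_name:
                    return a
                names.append(a.name)
        if names:
            raise KeyError(
                f"{self.id}: residue {resnum}{icode} has no atom "
                f"{atom_name!r}; available: {sorted(set(names))}")
        raise KeyError(f"{self.id}: no residue {resnum}{icode}")

    def ca_coords(self, residues: Iterable[ResKey] | None = None) -> np.ndarray:
        """(M, 3) array of C-alpha positions for the given residue keys."""
        table = {a.reskey: a.xyz for a in self.atoms
                 if not a.is_hetero and a.name == "CA"}
        keys = list(residues) if residues is not None else self.ca_residues()
        missing = [k for k in keys if k not in table]
        if missing:
            raise KeyError(f"{self.id}: no C-alpha for residues {missing}")
        return np.array([table[k] for k in keys], dtype=float)

    def hetero_groups(self) -> list[str]:
        return sorted({a.resname for a in self.atoms if a.is_hetero})


def read_structure(path: str | Path, chain: str | None = None,
                   model_index: int = 0) -> StructureModel:
    """Read one chain from a PDB or mmCIF file.

    Waters are excluded; other hetero groups (ligands) are retained and
    flagged. Alternate locations are resolved to the highest-occupancy
    conformer per atom name.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: file contains no models")
    if model_index >= len(st):
        raise IndexError(f"{path}: model index {model_index} out of range "
                         f"(file has {len(st)} models)")
    model = st[model_index]
    chains = [ch.name for ch in model]
    if not chains:
        raise ValueError(f"{path}: no chains parsed; not a valid PDB/mmCIF "
                         "file or empty model")
    if chain is None:
        if len(chains) != 1:
            raise ValueError(f"{path}: multiple chains {chains}; "
                             "specify one explicitly")
        chain = chains[0]
    if chain not in chains:
        raise KeyError(f"{path}: no chain {chain!r}; available: {chains}")

    atoms: list[Atom] = []
    for res in model[chain]:
        if res.name in WATER_NAMES:
            continue
        is_het = res.het_flag == "H"
        # resolve altlocs: keep the highest-occupancy conformer per atom name
        best: dict[str, gemmi.Atom] = {}
        for at in res:
            prev = best.get(at.name)
            if prev is None or at.occ > prev.occ:
                best[at.name] = at
        for at in best.values():
            atoms.append(Atom(
                chain=chain, resnum=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                resname=res.name, name=at.name,
                element=at.element.name,
                pos=(at.pos.x, at.pos.y, at.pos.z),
                occupancy=at.occ, is_hetero=is_het))
    if not any(a.name == "CA" and not a.is_hetero for a in atoms):
        raise ValueError(f"{path} chain {chain}: no polymer C-alpha atoms")
    return StructureModel(id=f"{path.stem}:{chain}", atoms=atoms)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model as a minimal single-chain PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.id
    md = gemmi.Model("1")
    by_res: dict[tuple[ResKey, str, bool], list[Atom]] = {}
    for a in model.atoms:
        by_res.setdefault((a.reskey, a.resname, a.is_hetero), []).append(a)
    ch = gemmi.Chain(model.atoms[0].chain if model.atoms else "A")
    for ((num, icode), resname, is_het), group in by_res.items():
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(num, icode or " ")
        res.het_flag = "H" if is_het else "A"
        for a in group:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element or a.name[0])
            at.pos = gemmi.Position(*a.pos)
            at.occ = a.occupancy
            res.add_atom(at)
        ch.add_residue(res)
    md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# residue maps
# ---------------------------------------------------------------------------

@dataclass
class ResidueMap:
    """Mapping from a structure's native numbering to the canonical frame.

    ``pairs`` maps native residue keys to canonical residue numbers. Keys may
    be plain integers (insertion code '') or (number, icode) tuples.
    """

    id: str
    pairs: dict[ResKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[ResKey, int] = {}
        for k, v in self.pairs.items():
            key = (int(k), "") if isinstance(k, (int, np.integer)) else (int(k[0]), str(k[1]))
            norm[key] = int(v)
        targets = list(norm.values())
        if len(set(targets)) != len(targets):
            dup = sorted({t for t in targets if targets.count(t) > 1})
            raise ValueError(f"residue map {self.id}: collisions onto "
                             f"canonical residues {dup}")
        self.pairs = norm

    @classmethod
    def identity(cls, map_id: str, residues: Iterable[int]) -> "ResidueMap":
        return cls(map_id, {(int(r), ""): int(r) for r in residues})

    @classmethod
    def from_json(cls, path: str | Path, map_id: str) -> "ResidueMap":
        data = json.loads(Path(path).read_text())
        if map_id not in data:
            raise KeyError(f"{path}: no residue map for {map_id!r}; "
                           f"available: {sorted(data)}")
        entry = data[map_id]
        pairs: dict[ResKey, int] = {}
        for k, v in entry.items():
            num, _, icode = k.partition("|")
            pairs[(int(num), icode)] = int(v)
        return cls(map_id, pairs)


def apply_residue_map(s: StructureModel, m: ResidueMap) -> StructureModel:
    """Renumber a structure into the canonical frame.

    Unmapped polymer residues are dropped (and logged); hetero groups keep
    their native numbering, as ligands are addressed by name.
    """
    out: list[Atom] = []
    dropped: set[ResKey] = set()
    for a in s.atoms:
        if a.is_hetero:
            out.append(a)
            continue
        canon = m.pairs.get(a.reskey)
        if canon is None:
            dropped.add(a.reskey)
            continue
        out.append(replace(a, resnum=canon, icode=""))
    if dropped:
        logger.info("%s: residue map %s dropped %d unmapped residues: %s",
                    s.id, m.id, len(dropped), sorted(dropped))
    return StructureModel(id=s.id, atoms=out)


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------

#: canonical PPDK domain boundaries (F. trinervia numbering)
DEFAULT_DOMAINS: dict[str, list[tuple[int, int]]] = {
    "NBD": [(1, 340)],
    "NBD1": [(1, 111), (197, 243)],
    "NBD2": [(112, 196)],
    "NBD3": [(244, 340)],
    "CD": [(380, 515)],
    "PBD": [(535, 874)],
    "LD": [(341, 379), (516, 534)],
}


@dataclass
class DomainDefinition:
    """Named residue ranges in the canonical frame."""

    ranges: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_DOMAINS.items()})

    def residues(self, name: str) -> list[int]:
        if name not in self.ranges:
            raise KeyError(f"unknown domain {name!r}; "
                           f"available: {sorted(self.ranges)}")
        out: list[int] = []
        for lo, hi in self.ranges[name]:
            out.extend(range(lo, hi + 1))
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "DomainDefinition":
        data = json.loads(Path(path).read_text())
        return cls({name: [tuple(r) for r in rngs] for name, rngs in data.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {k: [list(r) for r in v] for k, v in self.ranges.items()}, indent=1))


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleAlignment:
    """Common-residue, optionally superposed C-alpha stack for N structures."""

    member_ids: list[str]
    residues: list[ResKey]
    coords: np.ndarray  # (N, M, 3)
    fitted: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n, m = len(self.member_ids), len(self.residues)
        if self.coords.shape != (n, m, 3):
            raise ValueError(f"coordinate stack shape {self.coords.shape} "
                             f"!= ({n}, {m}, 3)")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_indices(self, residues: Iterable[int]) -> np.ndarray:
        """Column indices of the given canonical residue numbers (present only)."""
        want = set(residues)
        return np.array([i for i, (num, _) in enumerate(self.residues)
                         if num in want], dtype=int)


def common_residues(models: Sequence[StructureModel]) -> list[ResKey]:
    sets = [set(m.ca_residues()) for m in models]
    inter = set.intersection(*sets)
    # keep the order of the first member
    return [k for k in models[0].ca_residues() if k in inter]


def build_ensemble(models: Sequence[StructureModel],
                   fit_set: Iterable[int] | None = None,
                   reference: str = "mean") -> EnsembleAlignment:
    """Stack C-alpha coordinates over the residues common to all members and
    superpose each member onto the reference over the fit set.

    ``reference`` is a member id, or "mean" for iterative fitting to the
    running ensemble average. ``fit_set`` is a set of canonical residue
    numbers; default is the full common set.
    """
    from .geometry import superpose  # local import to avoid cycle

    if len(models) < 2:
        raise ValueError("need at least two structures to build an ensemble")
    common = common_residues(models)
    if not common:
        cov = {m.id: len(m.ca_residues()) for m in models}
        raise ValueError("no residues common to all members; per-member "
                         f"C-alpha coverage: {cov}")
    coords = np.stack([m.ca_coords(common) for m in models])
    ids = [m.id for m in models]

    if fit_set is None:
        idx = np.arange(len(common))
    else:
        want = set(fit_set)
        idx = np.array([i for i, (num, _) in enumerate(common) if num in want],
                       dtype=int)
        if len(idx) < 3:
            raise ValueError("fit set covers fewer than 3 common residues")

    if reference == "mean":
        # fit to first member, then refit everyone to the running mean twice
        ref = coords[0, idx]
        for _ in range(3):
            for i in range(len(coords)):
                sup = superpose(coords[i, idx], ref)
                coords[i] = sup.apply(coords[i])
            ref = coords[:, idx].mean(axis=0)
    else:
        if reference not in ids:
            raise KeyError(f"reference {reference!r} not among members {ids}")
        ref = coords[ids.index(reference), idx]
        for i in range(len(coords)):
            sup = superpose(coords[i, idx], ref)
            coords[i] = sup.apply(coords[i])
    return EnsembleAlignment(ids, common, coords, fitted=True)


# ---------------------------------------------------------------------------
# ensemble archive (documented text layout)
# ---------------------------------------------------------------------------

def write_ensemble(e: EnsembleAlignment, path: str | Path) -> None:
    """Write an ensemble as a portable text archive.

    Layout: a JSON header line (member ids, residues, fitted flag) followed
    by one whitespace-delimited line of 3M floats per member.
    """
    path = Path(path)
    header = {"member_ids": e.member_ids,
              "residues": [[n, i] for n, i in e.residues],
              "fitted": e.fitted}
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for row in e.coords.reshape(e.n_members, -1):
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def read_ensemble(path: str | Path) -> EnsembleAlignment:
    path = Path(path)
    with path.open() as fh:
        header = json.loads(fh.readline())
        rows = [np.fromstring(line, sep=" ") for line in fh if line.strip()]
    residues = [(int(n), str(i)) for n, i in header["residues"]]
    coords = np.array(rows).reshape(len(header["member_ids"]), len(residues), 3)
    return EnsembleAlignment(header["member_ids"], residues, coords,
                             fitted=bool(header["fitted"]))
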