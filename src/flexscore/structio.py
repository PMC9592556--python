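"""File I/O: multi-model PDB/mmCIF structures, NMR-STAR chemical-shift
loops, and tab-separated segment-mapping tables.

Structure parsing is delegated to :mod:`gemmi`; the NMR-STAR reader is a
small purpose-built parser for the v3.1 assigned-chemical-shift loop (only
the loop tags this package needs are interpreted).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from .types import (
    Atom,
    BACKBONE_NUCLEI,
    ChemicalShiftSet,
    Model,
    SegmentMapping,
    StructureEnsemble,
)

logger = logging.getLogger(__name__)

AMIDE_NH_LENGTH = 1.01  # Angstrom, standard N-H bond length


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure(path, format: Optional[str] = None) -> StructureEnsemble:
    """Read a (possibly multi-model) structure file into an ensemble.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"pdb", "mmcif", None}
        Explicit format; ``None`` infers from the extension.

    Every MODEL record becomes one ensemble member.  The B-factor column is
    retained verbatim (predicted models store pLDDT there).  HETATM records
    are kept but flagged ``hetero`` so the rigidity network can exclude
    ligands by default.  Residues with insertion codes are rejected; for
    alternate locations the first altloc is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path} as {format}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    st.setup_entities()
    models: List[Model] = []
    for model in st:
        atoms: Model = []
        for chain in model:
            for res in chain:
                if res.seqid.icode not in (" ", "", "\x00"):
                    raise ValueError(
                        f"{path}: residue {res.seqid.num}{res.seqid.icode} has an "
                        "insertion code; renumber the file first"
                    )
                seen_names: set = set()
                for atom in res:
                    if atom.name in seen_names:  # keep first altloc only
                        continue
                    seen_names.add(atom.name)
                    atoms.append(Atom(
                        name=atom.name,
                        element=atom.element.name,
                        res_seq=res.seqid.num,
                        res_name=res.name,
                        chain_id=chain.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        bfactor=float(atom.b_iso),
                        hetero=res.het_flag == "H",
                    ))
        if atoms:
            models.append(atoms)
    if not models:
        raise ValueError(f"{path}: no atoms found")
    return StructureEnsemble(models, source_id=path.stem)


def write_structure(ens: StructureEnsemble, path, format: str = "pdb") -> None:
    """Write an ensemble as a multi-MODEL PDB (or mmCIF) file."""
    st = gemmi.Structure()
    st.name = ens.source_id or "flexscore"
    for i, model in enumerate(ens.models, start=1):
        gm = gemmi.Model(i)
        chains: Dict[str, gemmi.Chain] = {}
        for a in model:
            ch = chains.get(a.chain_id)
            if ch is None:
                ch = gemmi.Chain(a.chain_id)
                chains[a.chain_id] = ch
            if len(ch) == 0 or ch[-1].seqid.num != a.res_seq or ch[-1].name != a.res_name:
                res = gemmi.Residue()
                res.name = a.res_name
                res.seqid = gemmi.SeqId(a.res_seq, " ")
                res.het_flag = "H" if a.hetero else "A"
                ch.add_residue(res)
            res = ch[-1]
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.b_iso = a.bfactor
            at.occ = 1.0
            res.add_atom(at)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    if format == "pdb":
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def extract_region(ens: StructureEnsemble, ranges: Sequence[Tuple[int, int]],
                   chain_id: Optional[str] = None) -> StructureEnsemble:
    """Restrict an ensemble to the union of inclusive residue intervals,
    preserving the original numbering."""
    return ens.extract_region(ranges, chain_id=chain_id)


# ---------------------------------------------------------------------------
# backbone amide hydrogens
# ---------------------------------------------------------------------------

def place_backbone_amide_hydrogens(model: Model) -> Model:
    """Add one amide H per eligible backbone N.

    The proton is placed 1.01 A from N along the reversed bisector of the
    N->CA and N->C(prev) directions (the standard in-plane trans-amide
    position).  Residues that already carry an amide H, prolines, hetero
    residues, and chain N-termini (no preceding residue ``res_seq - 1`` in
    the same chain) are left untouched.  Existing atoms are never moved.
    """
    out = [a.copy() for a in model]
    # index backbone atoms per (chain, residue)
    bb: Dict[Tuple[str, int], Dict[str, Atom]] = {}
    resnames: Dict[Tuple[str, int], str] = {}
    has_h: set = set()
    for a in out:
        key = (a.chain_id, a.res_seq)
        resnames[key] = a.res_name
        if a.name in ("N", "CA", "C"):
            bb.setdefault(key, {})[a.name] = a
        if a.name == "H":
            has_h.add(key)
        if a.hetero:
            bb.pop(key, None)
    placed: List[Atom] = []
    for (chain, res), atoms in bb.items():
        if (chain, res) in has_h or resnames[(chain, res)] == "PRO":
            continue
        prev = bb.get((chain, res - 1))
        if prev is None or "C" not in prev:
            continue  # chain N-terminus
        if "N" not in atoms or "CA" not in atoms:
            logger.warning("residue %s%d lacks backbone atoms; H not placed", chain, res)
            continue
        n, ca, cprev = atoms["N"].coords, atoms["CA"].coords, prev["C"].coords
        u = ca - n
        v = cprev - n
        u = u / np.linalg.norm(u)
        v = v / np.linalg.norm(v)
        d = -(u + v)
        nrm = np.linalg.norm(d)
        if nrm < 1e-8:
            logger.warning("degenerate geometry at residue %s%d; H not placed", chain, res)
            continue
        h = n + AMIDE_NH_LENGTH * d / nrm
        placed.append(Atom(
            name="H", element="H", res_seq=res,
            res_name=resnames[(chain, res)], chain_id=chain,
            coords=h, bfactor=atoms["N"].bfactor,
        ))
    # insert each H directly after its residue's N for tidy output
    result: Model = []
    by_res: Dict[Tuple[str, int], Atom] = {(h.chain_id, h.res_seq): h for h in placed}
    for a in out:
        result.append(a)
        if a.name == "N" and (a.chain_id, a.res_seq) in by_res:
            result.append(by_res.pop((a.chain_id, a.res_seq)))
    result.extend(by_res.values())
    return result


# ---------------------------------------------------------------------------
# NMR-STAR chemical shifts
# ---------------------------------------------------------------------------

_STAR_TAGS = ("Seq_ID", "Comp_ID", "Atom_ID", "Val")


def read_shifts(path) -> ChemicalShiftSet:
    """Read an NMR-STAR v3.1 assigned-chemical-shift loop.

    Only ``_Atom_chem_shift`` loops are interpreted; atom types outside the
    backbone set {N, H, CA, CB, C, HA} are ignored.  A duplicate
    (residue, atom) key with conflicting values is an error.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    i = 0
    entries: Dict[Tuple[int, str], float] = {}
    seq: Dict[int, str] = {}
    found_loop = False
    while i < len(lines):
        if lines[i] != "loop_":
            i += 1
            continue
        i += 1
        raw_tags: List[str] = []
        while i < len(lines) and lines[i].startswith("_"):
            raw_tags.append(lines[i].split()[0])
            i += 1
        tags = [t.split(".")[-1] for t in raw_tags]
        if not raw_tags or not all(t.startswith("_Atom_chem_shift") for t in raw_tags):
            # not a shift loop; skip to stop_
            while i < len(lines) and lines[i] != "stop_":
                i += 1
            continue
        try:
            idx = {t: tags.index(t) for t in _STAR_TAGS}
        except ValueError as exc:
            raise ValueError(f"{path}: shift loop missing tag: {exc}") from exc
        found_loop = True
        while i < len(lines) and lines[i] != "stop_":
            if not lines[i] or lines[i].startswith("#"):
                i += 1
                continue
            fields = lines[i].split()
            if len(fields) < len(tags):
                raise ValueError(f"{path}: malformed shift row: {lines[i]!r}")
            res = int(fields[idx["Seq_ID"]])
            comp = fields[idx["Comp_ID"]].upper()
            atom = fields[idx["Atom_ID"]].upper()
            val_s = fields[idx["Val"]]
            i += 1
            if atom not in BACKBONE_NUCLEI or val_s in (".", "?"):
                continue
            val = float(val_s)
            key = (res, atom)
            if key in entries and abs(entries[key] - val) > 1e-6:
                raise ValueError(
                    f"{path}: conflicting duplicate shift for residue {res} atom "
                    f"{atom}: {entries[key]} vs {val}"
                )
            entries[key] = val
            seq.setdefault(res, comp)
        i += 1
    if not found_loop:
        raise ValueError(f"{path}: no _Atom_chem_shift loop found")
    return ChemicalShiftSet(entries, seq)


def write_shifts(shifts: ChemicalShiftSet, path, entry_id: str = "synthetic") -> None:
    """Write a ChemicalShiftSet as a minimal NMR-STAR v3.1 file."""
    lines = [
        f"data_{entry_id}",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.ID            1",
        "",
        "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Seq_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Val",
        "",
    ]
    i = 1
    for (res, atom), val in sorted(shifts.entries.items()):
        comp = shifts.seq.get(res, "UNK")
        lines.append(f"      {i:<5d} {res:<5d} {comp:<4s} {atom:<4s} {val:.3f}")
        i += 1
    lines += ["   stop_", "save_", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# segment mappings (SIFTS-style TSV)
# ---------------------------------------------------------------------------

_MAPPING_COLS = ["uniprot_acc", "pdb_id", "chain_id", "pdb_start", "pdb_end",
                 "uniprot_start", "uniprot_end"]


def read_segment_mappings(path) -> List[SegmentMapping]:
    """Read a tab-separated segment-mapping table (SIFTS-style)."""
    df = pd.read_csv(path, sep="\t", dtype={"uniprot_acc": str, "pdb_id": str,
                                            "chain_id": str})
    missing = [c for c in _MAPPING_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mapping table missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(SegmentMapping(
            uniprot_acc=row.uniprot_acc,
            pdb_id=row.pdb_id,
            chain_id=row.chain_id,
            pdb_range=(int(row.pdb_start), int(row.pdb_end)),
            uniprot_range=(int(row.uniprot_start), int(row.uniprot_end)),
        ))
    return out


def write_segment_mappings(segments: Iterable[SegmentMapping], path) -> None:
    rows = [{
        "uniprot_acc": s.uniprot_acc, "pdb_id": s.pdb_id, "chain_id": s.chain_id,
        "pdb_start": s.pdb_range[0], "pdb_end": s.pdb_range[1],
        "uniprot_start": s.uniprot_range[0], "uniprot_end": s.uniprot_range[1],
    } for s in segments]
    pd.DataFrame(rows, columns=_MAPPING_COLS).to_csv(path, sep="\t", index=False)
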