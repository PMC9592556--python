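"""Core in-memory containers shared by every stage of the analysis.

The data model is deliberately small: an :class:`Atom` is a plain record, a
:class:`StructureEnsemble` is an ordered list of models (lists of atoms) plus
residue bookkeeping, and a :class:`ChemicalShiftSet` maps ``(residue, atom
type)`` keys to shifts in ppm.  Everything downstream (rigidity networks,
flexibility profiles, scores) is derived from these three.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

#: Backbone nuclei considered throughout the package.
BACKBONE_NUCLEI: Tuple[str, ...] = ("N", "H", "CA", "CB", "C", "HA")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass
class Atom:
    """One atom record.

    ``bfactor`` carries the PDB B-factor verbatim; for predicted models this
    is the per-residue confidence (pLDDT, 0-100).  ``hetero`` marks HETATM
    records so ligand exclusion can be applied when building bond networks.
    """

    name: str
    element: str
    res_seq: int
    res_name: str
    chain_id: str
    coords: np.ndarray
    bfactor: float = 0.0
    hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name} has invalid coordinates")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


Model = List[Atom]


class StructureEnsemble:
    """One or more models (conformers) of the same polymer.

    All models must share the same set of ``(chain_id, res_seq, res_name)``
    residues; per-model atom counts may differ only in hydrogens.
    """

    def __init__(self, models: Sequence[Model], source_id: str = ""):
        if len(models) == 0:
            raise ValueError("ensemble must contain at least one model")
        self.models: List[Model] = [list(m) for m in models]
        self.source_id = source_id
        ref = self._residue_set(self.models[0])
        for i, m in enumerate(self.models[1:], start=2):
            if self._residue_set(m) != ref:
                raise ValueError(
                    f"model {i} does not share the residue set of model 1"
                )

    @staticmethod
    def _residue_set(model: Model) -> frozenset:
        return frozenset((a.chain_id, a.res_seq, a.res_name) for a in model)

    # -- residue bookkeeping -------------------------------------------------

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def chain_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for a in self.models[0]:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def seq(self, chain_id: Optional[str] = None) -> Dict[int, str]:
        """Residue-number -> 3-letter code map for one chain.

        Hetero-only residues (waters, ligands) are excluded.
        """
        chain_id = self._resolve_chain(chain_id)
        out: Dict[int, str] = {}
        for a in self.models[0]:
            if a.chain_id == chain_id and not a.hetero:
                out.setdefault(a.res_seq, a.res_name)
        return dict(sorted(out.items()))

    def residue_numbers(self, chain_id: Optional[str] = None) -> List[int]:
        return sorted(self.seq(chain_id))

    def _resolve_chain(self, chain_id: Optional[str]) -> str:
        chains = self.chain_ids
        if chain_id is None:
            if len(chains) > 1:
                raise ValueError(
                    f"ensemble has chains {chains}; an explicit chain is required"
                )
            return chains[0]
        if chain_id not in chains:
            raise ValueError(f"chain {chain_id!r} not present (have {chains})")
        return chain_id

    def select_chain(self, chain_id: str) -> "StructureEnsemble":
        chain_id = self._resolve_chain(chain_id)
        models = [[a.copy() for a in m if a.chain_id == chain_id] for m in self.models]
        return StructureEnsemble(models, source_id=self.source_id)

    def extract_region(self, ranges: Iterable[Tuple[int, int]],
                       chain_id: Optional[str] = None) -> "StructureEnsemble":
        """Restrict to the union of inclusive residue intervals."""
        chain_id = self._resolve_chain(chain_id)
        present = set(self.seq(chain_id))
        keep: set = set()
        for lo, hi in ranges:
            hit = {r for r in present if lo <= r <= hi}
            if not hit:
                raise ValueError(f"interval [{lo}, {hi}] matches no residue")
            keep |= hit
        models = [
            [a.copy() for a in m if a.chain_id == chain_id and a.res_seq in keep]
            for m in self.models
        ]
        return StructureEnsemble(models, source_id=self.source_id)

    def renumber(self, offset: int) -> "StructureEnsemble":
        """Shift every residue number by ``offset`` (used for segment mapping)."""
        models = []
        for m in self.models:
            mm = []
            for a in m:
                b = a.copy()
                b.res_seq = a.res_seq + offset
                mm.append(b)
            models.append(mm)
        return StructureEnsemble(models, source_id=self.source_id)


class ChemicalShiftSet:
    """Backbone chemical shifts keyed by ``(res_seq, atom_type)`` in ppm."""

    SHIFT_RANGE = (-10.0, 250.0)

    def __init__(self, entries: Mapping[Tuple[int, str], float],
                 seq: Mapping[int, str]):
        self.entries: Dict[Tuple[int, str], float] = {}
        for (res, atom), val in entries.items():
            if atom not in BACKBONE_NUCLEI:
                continue
            v = float(val)
            lo, hi = self.SHIFT_RANGE
            if not (lo <= v <= hi):
                raise ValueError(f"shift {v} ppm for {(res, atom)} out of range")
            self.entries[(int(res), atom)] = v
        self.seq: Dict[int, str] = dict(sorted((int(k), v) for k, v in seq.items()))

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, res_seq: int, atom: str) -> Optional[float]:
        return self.entries.get((res_seq, atom))

    def residues(self) -> List[int]:
        return sorted({r for r, _ in self.entries})

    def restrict(self, residues: Iterable[int]) -> "ChemicalShiftSet":
        keep = set(residues)
        return ChemicalShiftSet(
            {k: v for k, v in self.entries.items() if k[0] in keep},
            {r: c for r, c in self.seq.items() if r in keep},
        )


@dataclass(frozen=True)
class SegmentMapping:
    """Residue-level correspondence between a reference (UniProt-style)
    numbering and one chain of a deposited structure."""

    uniprot_acc: str
    pdb_id: str
    chain_id: str
    pdb_range: Tuple[int, int]
    uniprot_range: Tuple[int, int]

    def __post_init__(self) -> None:
        (ps, pe), (us, ue) = self.pdb_range, self.uniprot_range
        if pe < ps or ue < us:
            raise ValueError("segment ranges must be non-empty")
        if pe - ps != ue - us:
            raise ValueError("pdb and uniprot ranges must have equal length")

    @property
    def offset(self) -> int:
        """uniprot residue number = pdb residue number + offset."""
        return self.uniprot_range[0] - self.pdb_range[0]

    def __len__(self) -> int:
        return self.pdb_range[1] - self.pdb_range[0] + 1


@dataclass
class PairCandidate:
    """One predicted-vs-NMR comparison candidate: the deposited ensemble,
    its backbone shifts, the single predicted model (confidence in the
    B-factor column), and the segment mappings tying the two numbering
    frames together.  ``well_defined`` intervals (NMR numbering) are input
    (the package does not re-derive them)."""

    uniprot_acc: str
    nmr_ensemble: StructureEnsemble
    predicted_model: StructureEnsemble
    shifts: ChemicalShiftSet
    segments: List[SegmentMapping]
    well_defined: Optional[List[Tuple[int, int]]] = None

    def __post_init__(self) -> None:
        ids = {(s.pdb_id, s.chain_id) for s in self.segments}
        if len(ids) > 1:
            raise ValueError(f"segments reference multiple chains: {ids}")
        if self.predicted_model.n_models != 1:
            raise ValueError("predicted side must be a single model")

    @property
    def chain_id(self) -> str:
        return self.segments[0].chain_id if self.segments else "A"


class FlexibilityProfile:
    """Per-residue flexibility on the RCI scale (ppm^-1; higher = more
    flexible).  ``values`` maps residue number -> value; residues absent from
    ``values`` are undefined."""

    def __init__(self, values: Mapping[int, float]):
        self.values: Dict[int, float] = {}
        for r, v in values.items():
            v = float(v)
            if not np.isfinite(v):
                raise ValueError(f"non-finite flexibility at residue {r}")
            self.values[int(r)] = v
        self.values = dict(sorted(self.values.items()))

    def __len__(self) -> int:
        return len(self.values)

    def defined(self) -> List[int]:
        return list(self.values)

    def get(self, res: int) -> Optional[float]:
        return self.values.get(res)

    def as_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        res = np.array(list(self.values), dtype=int)
        val = np.array([self.values[r] for r in res], dtype=float)
        return res, val

    def restrict(self, residues: Iterable[int]) -> "FlexibilityProfile":
        keep = set(residues)
        return FlexibilityProfile({r: v for r, v in self.values.items() if r in keep})

    def renumber(self, offset: int) -> "FlexibilityProfile":
        return FlexibilityProfile({r + offset: v for r, v in self.values.items()})
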