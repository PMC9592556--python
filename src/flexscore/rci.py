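"""Per-residue flexibility from backbone chemical shifts (the random coil
index route).

The random coil index (RCI) expresses how far each residue's backbone shifts
sit from their random-coil reference values: residues in regular secondary
structure show large secondary shifts and therefore a *small* RCI, while
disordered residues have near-zero secondary shifts and an RCI pinned at the
cap.  The per-residue statistic is

    s_i  = sum_n  w_n * |dd_{i,n}|        over the nuclei observed at i
    RCI_i = min( 1 / max(s_i, floor),  cap )

with ``dd`` the secondary shift (observed minus random coil, minus optional
nearest-neighbour corrections), then smoothed by a short centred moving
average over the defined residues.  The weighted sum is deliberately *not*
normalised by the number of observed nuclei: a residue with several large
secondary shifts is more confidently structured than one with a single large
shift, and the resulting scale puts helix/sheet residues near 0.1-0.2 ppm^-1
and coil at the cap, which is the scale the structure-route profile is
rescaled onto.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .types import BACKBONE_NUCLEI, ChemicalShiftSet, FlexibilityProfile

logger = logging.getLogger(__name__)

#: residues that chemically lack a given nucleus
ABSENT_NUCLEI = {("GLY", "CB"), ("PRO", "H")}  # no CB on glycine, no HN on proline

#: parent-residue mapping for common non-standard residues
NONSTANDARD_PARENT = {
    "MSE": "MET", "HYP": "PRO", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "MLY": "LYS", "M3L": "LYS", "FME": "MET", "CME": "CYS",
}


class RandomCoilTable:
    """Random-coil reference shifts (ppm) per (residue code, nucleus), with
    optional nearest-neighbour corrections per (neighbour code, nucleus,
    offset in {-1, +1})."""

    def __init__(self, values: Mapping[Tuple[str, str], float],
                 corrections: Optional[Mapping[Tuple[str, str, int], float]] = None):
        self.values = {(r.upper(), a.upper()): float(v) for (r, a), v in values.items()}
        self.corrections = {
            (r.upper(), a.upper(), int(o)): float(v)
            for (r, a, o), v in (corrections or {}).items()
        }

    @classmethod
    def default(cls) -> "RandomCoilTable":
        """The packaged table (standard random-coil literature values)."""
        with resources.files("flexscore.data").joinpath(
                "random_coil_shifts.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", na_values=".")
        vals: Dict[Tuple[str, str], float] = {}
        for row in df.itertuples(index=False):
            for nuc in BACKBONE_NUCLEI:
                v = getattr(row, nuc)
                if pd.notna(v):
                    vals[(row.res, nuc)] = float(v)
        return cls(vals)

    def reference(self, res_name: str, nucleus: str) -> Optional[float]:
        res_name = res_name.upper()
        if (res_name, nucleus) in self.values:
            return self.values[(res_name, nucleus)]
        parent = NONSTANDARD_PARENT.get(res_name)
        if parent is not None:
            return self.values.get((parent, nucleus))
        return None

    def correction(self, neighbor_code: str, nucleus: str, offset: int) -> float:
        return self.corrections.get((neighbor_code.upper(), nucleus, offset), 0.0)


@dataclass
class RciOptions:
    """Tunable parameters of the RCI computation (all config-exposed)."""

    weights: Dict[str, float] = field(default_factory=lambda: {
        "CA": 1.0, "CB": 1.0, "C": 1.0, "N": 0.6, "H": 0.6, "HA": 1.0,
    })
    smoothing_window: int = 3
    cap: float = 0.6            # ppm^-1, maximum (coil-limit) RCI
    floor: float = 0.5          # ppm, minimum weighted secondary-shift sum
    min_nuclei_per_residue: int = 2
    apply_neighbor_corrections: bool = False

    def __post_init__(self) -> None:
        if all(w == 0 for w in self.weights.values()):
            raise ValueError("weights must not all be zero")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if self.cap <= 0:
            raise ValueError("cap must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


def expected_pairs(seq: Mapping[int, str], nuclei: Iterable[str]) -> Set[Tuple[int, str]]:
    """(residue, nucleus) pairs a complete assignment would contain,
    excluding chemically absent atoms."""
    out = set()
    for res, code in seq.items():
        code = NONSTANDARD_PARENT.get(code.upper(), code.upper())
        for nuc in nuclei:
            if (code, nuc) not in ABSENT_NUCLEI:
                out.add((res, nuc))
    return out


def completeness(shifts: ChemicalShiftSet, seq: Mapping[int, str],
                 nuclei: Iterable[str] = BACKBONE_NUCLEI) -> float:
    """Fraction of expected (residue, nucleus) assignments that are present."""
    if not seq:
        raise ValueError("empty sequence")
    expected = expected_pairs(seq, nuclei)
    if not expected:
        return 0.0
    present = sum(1 for key in expected if key in shifts.entries)
    return present / len(expected)


def secondary_shifts(shifts: ChemicalShiftSet, table: RandomCoilTable,
                     apply_neighbor_corrections: bool = False,
                     ) -> Dict[Tuple[int, str], float]:
    """Observed minus random-coil (plus optional neighbour-correction) shifts.

    Residues whose code has no table entry (and no declared parent) yield no
    entries; standard residues missing from the table raise.
    """
    out: Dict[Tuple[int, str], float] = {}
    for (res, nuc), obs in shifts.entries.items():
        code = shifts.seq.get(res, "UNK").upper()
        ref = table.reference(code, nuc)
        if ref is None:
            parent = NONSTANDARD_PARENT.get(code)
            if code in ("UNK",) or parent is None and (code, "CA") not in table.values:
                # unknown / non-standard residue without a parent: undefined
                continue
            raise ValueError(f"residue {res} ({code}): no random-coil value for {nuc}")
        corr = 0.0
        if apply_neighbor_corrections:
            for off in (-1, +1):
                ncode = shifts.seq.get(res + off)
                if ncode is not None:
                    corr += table.correction(ncode, nuc, off)
        out[(res, nuc)] = obs - (ref + corr)
    return out


def rereference(shifts: ChemicalShiftSet, table: RandomCoilTable,
                min_residues: int = 10,
                ) -> Tuple[ChemicalShiftSet, Dict[str, float]]:
    """Correct systematic referencing offsets per nucleus.

    A referencing error shifts *every* residue of a nucleus by the same
    amount, whereas secondary structure shifts only the structured
    residues; estimating the offset over all residues would therefore
    misread a helix-rich protein's genuine +3 ppm CA shifts as a
    referencing error.  The offset for each nucleus is instead the median
    secondary shift over the most coil-like quarter of the residues
    (smallest mean absolute secondary shift across their observed nuclei),
    which is driven by the true coil residues as long as at least a quarter
    of the chain is disordered.  It is subtracted when its magnitude
    exceeds 0.5 ppm (heavy atoms) or 0.1 ppm (protons).  Nuclei observed on
    fewer than ``min_residues`` residues are left unchanged.  Returns the
    corrected copy and the applied offsets.
    """
    dd = secondary_shifts(shifts, table)
    per_res: Dict[int, List[float]] = {}
    for (r, n), v in dd.items():
        per_res.setdefault(r, []).append(abs(v))
    if not per_res:
        return shifts, {}
    agg = {r: float(np.mean(v)) for r, v in per_res.items()}
    cut = float(np.percentile(list(agg.values()), 25.0))
    coil_like = {r for r, u in agg.items() if u <= cut}
    offsets: Dict[str, float] = {}
    for nuc in BACKBONE_NUCLEI:
        all_vals = [v for (r, n), v in dd.items() if n == nuc]
        if len(all_vals) < min_residues:
            if all_vals:
                logger.warning("rereference: only %d residues carry %s; skipped",
                               len(all_vals), nuc)
            continue
        vals = [v for (r, n), v in dd.items() if n == nuc and r in coil_like]
        if len(vals) < 4:
            vals = all_vals
        med = float(np.median(vals))
        threshold = 0.1 if nuc in ("H", "HA") else 0.5
        if abs(med) > threshold:
            offsets[nuc] = med
    if not offsets:
        return shifts, {}
    corrected = {
        key: (val - offsets.get(key[1], 0.0))
        for key, val in shifts.entries.items()
    }
    return ChemicalShiftSet(corrected, shifts.seq), offsets


def rci_profile(dd: Mapping[Tuple[int, str], float],
                opts: Optional[RciOptions] = None) -> FlexibilityProfile:
    """Turn secondary shifts into a per-residue flexibility profile.

    Residues carrying fewer than ``min_nuclei_per_residue`` observed nuclei
    are undefined (never interpolated).
    """
    opts = opts or RciOptions()
    per_res: Dict[int, Dict[str, float]] = {}
    for (res, nuc), val in dd.items():
        per_res.setdefault(res, {})[nuc] = val
    s: Dict[int, float] = {}
    for res, nucs in per_res.items():
        usable = {n: v for n, v in nucs.items() if opts.weights.get(n, 0.0) > 0}
        if len(usable) < opts.min_nuclei_per_residue:
            continue
        s[res] = sum(opts.weights[n] * abs(v) for n, v in usable.items())
    if not s:
        raise ValueError(
            f"no residue carries >= {opts.min_nuclei_per_residue} usable nuclei"
        )
    residues = sorted(s)
    raw = np.array([s[r] for r in residues])
    # centred moving average over the sequence of defined residues
    w = opts.smoothing_window
    if w > 1 and len(raw) > 1:
        half = w // 2
        sm = np.empty_like(raw)
        for i in range(len(raw)):
            lo, hi = max(0, i - half), min(len(raw), i + half + 1)
            sm[i] = raw[lo:hi].mean()
    else:
        sm = raw
    rci = np.minimum(1.0 / np.maximum(sm, opts.floor), opts.cap)
    return FlexibilityProfile(dict(zip(residues, rci)))


def profile_from_shifts(shifts: ChemicalShiftSet,
                        table: Optional[RandomCoilTable] = None,
                        opts: Optional[RciOptions] = None,
                        do_rereference: bool = True) -> FlexibilityProfile:
    """Convenience route: shifts -> (re-reference) -> secondary shifts -> RCI."""
    table = table or RandomCoilTable.default()
    opts = opts or RciOptions()
    if do_rereference:
        shifts, offsets = rereference(shifts, table)
        if offsets:
            logger.info("re-referencing offsets applied: %s", offsets)
    dd = secondary_shifts(shifts, table,
                          apply_neighbor_corrections=opts.apply_neighbor_corrections)
    return rci_profile(dd, opts)


def write_profile(profile: FlexibilityProfile, path,
                  all_residues: Optional[Iterable[int]] = None) -> None:
    """Tab-separated (residue, value, defined) records."""
    residues = sorted(set(all_residues or []) | set(profile.defined()))
    rows = []
    for r in residues:
        v = profile.get(r)
        rows.append({"residue": r,
                     "value": "" if v is None else f"{v:.6f}",
                     "defined": v is not None})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
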