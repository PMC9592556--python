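"""Synthetic paired structure/shift fixtures with known ground truth.

The generator builds idealised protein backbones (N, CA, C, O, CB, amide H)
from internal coordinates: helix residues use phi/psi = -57/-47 deg (which
places the i -> i+4 carbonyl-amide pairs in hydrogen-bonding geometry),
strand residues -120/+120 deg, and coil residues draw broad random dihedrals
so that coil segments differ between ensemble models ("ill-defined"
regions).  Chains are finished with acetyl / N-methyl style capping groups
on the ideal backbone continuation so that every scored residue has both
phi and psi defined; caps carry residue numbers outside the scored range
and never enter sequence maps or profiles.

Chemical shifts are simulated as random-coil reference + a canonical
secondary-shift offset per secondary-structure class + Gaussian noise, then
thinned to an exact completeness target.  Hydrogen-bond degradation tips
amide protons into the backbone (rather than deleting atoms) so that a
chosen fraction of backbone hydrogen bonds fails the energy criterion while
the chemistry stays intact.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import structio
from .rci import ABSENT_NUCLEI, RandomCoilTable, expected_pairs
from .types import (
    AA1_TO_3,
    Atom,
    BACKBONE_NUCLEI,
    ChemicalShiftSet,
    Model,
    PairCandidate,
    SegmentMapping,
    StructureEnsemble,
)

# ideal backbone internal coordinates (A / deg)
BOND_N_CA, BOND_CA_C, BOND_C_N = 1.458, 1.525, 1.329
BOND_C_O, BOND_CA_CB = 1.231, 1.530
ANG_C_N_CA, ANG_N_CA_C, ANG_CA_C_N = 121.7, 111.2, 116.2
ANG_CA_C_O, ANG_N_CA_CB = 120.8, 110.5
OMEGA = 180.0

DIHEDRALS = {"H": (-57.0, -47.0), "E": (-120.0, 120.0)}

#: canonical secondary-shift offsets (ppm) used by the generator
SS_SHIFT_OFFSETS = {
    "H": {"CA": 3.0, "C": 2.0, "HA": -0.3},
    "E": {"CA": -1.5, "C": -1.5, "HA": 0.3},
    "C": {},
}

#: per-model coil dihedral jitter, degrees of standard deviation per A of
#: requested coil dispersion (documented heuristic)
COIL_JITTER_DEG_PER_A = 20.0


@dataclass
class SyntheticSpec:
    """Ground-truth description of one synthetic protein."""

    ss_string: str
    sequence: str
    n_models: int = 1
    shift_noise_sd: float = 0.0          # ppm
    completeness_target: float = 1.0
    hbond_retention: Union[float, Sequence[float]] = 1.0  # scalar or per model
    coil_dispersion: float = 1.0         # A
    plddt_profile: Optional[Sequence[float]] = None  # per residue, 0-100
    seed: int = 0
    first_residue: int = 1
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if len(self.ss_string) != len(self.sequence):
            raise ValueError("ss_string and sequence lengths differ")
        if self.plddt_profile is not None and len(self.plddt_profile) != len(self.sequence):
            raise ValueError("plddt_profile length differs from sequence")
        if not (0.0 <= self.completeness_target <= 1.0):
            raise ValueError("completeness_target must lie in [0, 1]")
        for ch in self.ss_string:
            if ch not in "HEC":
                raise ValueError(f"invalid secondary-structure code {ch!r}")
        # isolated single H/E cannot form a buildable motif
        s = self.ss_string
        for i, ch in enumerate(s):
            if ch in "HE":
                prev_same = i > 0 and s[i - 1] == ch
                next_same = i + 1 < len(s) and s[i + 1] == ch
                if not prev_same and not next_same:
                    raise ValueError(
                        f"isolated {ch!r} at position {i}: unbuildable motif")

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    def residue_numbers(self) -> List[int]:
        return list(range(self.first_residue, self.first_residue + self.n_res))

    def retention_for_model(self, m: int) -> float:
        if isinstance(self.hbond_retention, (int, float)):
            return float(self.hbond_retention)
        return float(self.hbond_retention[m])

    def seq_map(self) -> Dict[int, str]:
        return {num: AA1_TO_3[aa]
                for num, aa in zip(self.residue_numbers(), self.sequence)}

    def ss_segments(self, codes: str = "HE") -> List[Tuple[int, int]]:
        """Inclusive residue intervals of the structured (ground-truth
        well-defined) segments."""
        out: List[Tuple[int, int]] = []
        start = None
        nums = self.residue_numbers()
        for i, ch in enumerate(self.ss_string + "$"):
            if i < len(self.ss_string) and ch in codes:
                if start is None:
                    start = nums[i]
            else:
                if start is not None:
                    out.append((start, nums[i - 1]))
                    start = None
        return out


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given A-B-C, |C-D|, angle(B,C,D) and dihedral(A,B,C,D)."""
    ang = math.radians(angle_deg)
    tor = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phis: List[float], psis: List[float]
                    ) -> List[Dict[str, np.ndarray]]:
    """Backbone heavy atoms for ``len(phis)`` residues."""
    n = len(phis)
    res: List[Dict[str, np.ndarray]] = [{} for _ in range(n)]
    res[0]["N"] = np.zeros(3)
    res[0]["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANG_N_CA_C)
    res[0]["C"] = res[0]["CA"] + BOND_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])
    for i in range(n):
        if i > 0:
            res[i]["N"] = nerf(res[i - 1]["N"], res[i - 1]["CA"], res[i - 1]["C"],
                               BOND_C_N, ANG_CA_C_N, psis[i - 1])
            res[i]["CA"] = nerf(res[i - 1]["CA"], res[i - 1]["C"], res[i]["N"],
                                BOND_N_CA, ANG_C_N_CA, OMEGA)
            res[i]["C"] = nerf(res[i - 1]["C"], res[i]["N"], res[i]["CA"],
                               BOND_CA_C, ANG_N_CA_C, phis[i])
        res[i]["O"] = nerf(res[i]["N"], res[i]["CA"], res[i]["C"],
                           BOND_C_O, ANG_CA_C_O, psis[i] + 180.0)
        res[i]["CB"] = nerf(res[i]["C"], res[i]["N"], res[i]["CA"],
                            BOND_CA_CB, ANG_N_CA_CB, -122.6)
    return res


def build_structure(spec: SyntheticSpec) -> StructureEnsemble:
    """Build the (possibly multi-model) synthetic ensemble for a spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_res
    nums = spec.residue_numbers()
    seq3 = [AA1_TO_3[aa] for aa in spec.sequence]
    # per-structure coil base dihedrals (shared across models)
    base_phi, base_psi = [], []
    for ch in spec.ss_string:
        if ch in DIHEDRALS:
            base_phi.append(DIHEDRALS[ch][0])
            base_psi.append(DIHEDRALS[ch][1])
        else:
            # extended, polyproline-II-like coil baseline: disordered
            # segments rarely pack back against the structured core
            base_phi.append(float(rng.uniform(-130.0, -60.0)))
            base_psi.append(float(rng.uniform(110.0, 170.0)))
    # cap dihedrals continue the terminal secondary structure
    first_ss = spec.ss_string[0] if spec.ss_string[0] in DIHEDRALS else "E"
    last_ss = spec.ss_string[-1] if spec.ss_string[-1] in DIHEDRALS else "E"
    cap0 = DIHEDRALS[first_ss]
    cap1 = DIHEDRALS[last_ss]

    jitter_sd = COIL_JITTER_DEG_PER_A * spec.coil_dispersion
    models: List[Model] = []
    for m in range(spec.n_models):
        phis = [cap0[0]] + list(base_phi) + [cap1[0]]
        psis = [cap0[1]] + list(base_psi) + [cap1[1]]
        for i, ch in enumerate(spec.ss_string):
            if ch == "C" and jitter_sd > 0 and spec.n_models > 1:
                phis[i + 1] += float(rng.normal(0.0, jitter_sd))
                psis[i + 1] += float(rng.normal(0.0, jitter_sd))
        bb = _build_backbone(phis, psis)
        atoms: Model = []

        def add(name: str, element: str, pos: np.ndarray, num: int,
                res_name: str, bfac: float) -> None:
            atoms.append(Atom(name=name, element=element, res_seq=num,
                              res_name=res_name, chain_id=spec.chain_id,
                              coords=pos, bfactor=bfac))

        # caps are first built as full alanine-like residues so the amide-H
        # placement rule applies, then trimmed to ACE / NME atom sets
        cap_num0, cap_num1 = nums[0] - 1, nums[-1] + 1
        add("N", "N", bb[0]["N"], cap_num0, "ACE", 0.0)
        add("CA", "C", bb[0]["CA"], cap_num0, "ACE", 0.0)
        add("C", "C", bb[0]["C"], cap_num0, "ACE", 0.0)
        add("O", "O", bb[0]["O"], cap_num0, "ACE", 0.0)
        for i in range(n):
            b = bb[i + 1]
            plddt = (float(spec.plddt_profile[i])
                     if spec.plddt_profile is not None else 0.0)
            add("N", "N", b["N"], nums[i], seq3[i], plddt)
            add("CA", "C", b["CA"], nums[i], seq3[i], plddt)
            add("C", "C", b["C"], nums[i], seq3[i], plddt)
            add("O", "O", b["O"], nums[i], seq3[i], plddt)
            if seq3[i] != "GLY":
                add("CB", "C", b["CB"], nums[i], seq3[i], plddt)
        add("N", "N", bb[n + 1]["N"], cap_num1, "NME", 0.0)
        add("CA", "C", bb[n + 1]["CA"], cap_num1, "NME", 0.0)
        atoms = structio.place_backbone_amide_hydrogens(atoms)
        trimmed: Model = []
        for a in atoms:
            if a.res_name == "ACE" and a.name == "N":
                continue
            if a.name == "CA" and a.res_name in ("ACE", "NME"):
                a.name = "CH3"
            trimmed.append(a)
        atoms = _degrade_hbonds(trimmed, spec.retention_for_model(m), rng)
        models.append(atoms)
    return StructureEnsemble(models, source_id=f"synthetic_{spec.seed}")


def _degrade_hbonds(atoms: Model, retention: float,
                    rng: np.random.Generator) -> Model:
    """Tip a random (1 - retention) fraction of amide protons into the
    backbone so their hydrogen bonds fail the angular criterion."""
    if retention >= 1.0:
        return atoms
    by_res: Dict[int, Dict[str, Atom]] = {}
    for a in atoms:
        by_res.setdefault(a.res_seq, {})[a.name] = a
    donors = sorted(r for r, d in by_res.items() if "H" in d and "N" in d)
    n_spoil = int(round((1.0 - retention) * len(donors)))
    spoil = rng.choice(len(donors), size=n_spoil, replace=False) if n_spoil else []
    for k in spoil:
        d = by_res[donors[int(k)]]
        n, h = d["N"], d["H"]
        # reflect H through N: points between CA and the previous carbonyl
        h.coords = n.coords - (h.coords - n.coords)
    return atoms


# ---------------------------------------------------------------------------
# dedicated secondary-structure fixtures
# ---------------------------------------------------------------------------

def build_antiparallel_sheet(n_per_strand: int = 6, sequence: str = None,
                             chain_id: str = "A") -> Model:
    """Two ideal antiparallel beta strands as one chain (numbering gap
    between strands; no covalent link).  Registration is found by scanning
    the inter-strand offset for the largest number of amide-carbonyl pairs
    in hydrogen-bond geometry, so the fixture is deterministic."""
    if sequence is None:
        sequence = "V" * n_per_strand
    spec = SyntheticSpec(ss_string="E" * n_per_strand, sequence=sequence,
                         seed=0, chain_id=chain_id)
    strand1 = [a for a in build_structure(spec).models[0]]
    coords1 = np.array([a.coords for a in strand1])
    # a 180 deg rotation about the normal of the strand's mean plane maps
    # the strand onto an antiparallel copy; scan a rigid offset for the
    # largest number of amide/carbonyl contacts in either direction
    flip = np.diag([-1.0, -1.0, 1.0])
    center = coords1.mean(axis=0)
    n1 = [a.coords for a in strand1 if a.name == "N"]
    o1 = [a.coords for a in strand1 if a.name == "O"]
    no2 = [(a.name, a.coords) for a in strand1 if a.name in ("N", "O")]
    best: Tuple[int, np.ndarray] = (-1, np.zeros(3))
    for dx in np.arange(-8.0, 8.0, 0.25):
        for dy in np.arange(-6.5, 6.6, 0.25):
            for dz in (-1.0, -0.5, 0.0, 0.5, 1.0):
                shift = np.array([dx, dy, dz])
                hits = 0
                for name, c in no2:
                    moved = (flip @ (c - center)) + center + shift
                    targets = n1 if name == "O" else o1
                    hits += sum(1 for t in targets
                                if 2.75 <= np.linalg.norm(moved - t) <= 3.05)
                if hits > best[0]:
                    best = (hits, shift)
    shift = best[1]
    strand2: Model = []
    offset = n_per_strand + 4  # numbering gap => no peptide link, chain break
    for a in strand1:
        b = a.copy()
        b.coords = (flip @ (a.coords - center)) + center + shift
        b.res_seq = a.res_seq + offset
        strand2.append(b)
    model = [a.copy() for a in strand1] + strand2
    model = [a for a in model if a.name != "H"]
    return structio.place_backbone_amide_hydrogens(model)


# ---------------------------------------------------------------------------
# chemical shifts
# ---------------------------------------------------------------------------

def simulate_shifts(spec: SyntheticSpec,
                    table: Optional[RandomCoilTable] = None) -> ChemicalShiftSet:
    """Random-coil value + secondary-shift offset by ss class + noise,
    thinned to the completeness target (exact to the nearest entry)."""
    table = table or RandomCoilTable.default()
    rng = np.random.default_rng(spec.seed + 1)
    seq = spec.seq_map()
    nums = spec.residue_numbers()
    expected = sorted(expected_pairs(seq, BACKBONE_NUCLEI))
    entries: Dict[Tuple[int, str], float] = {}
    for res, nuc in expected:
        code = seq[res]
        ref = table.reference(code, nuc)
        if ref is None:
            continue
        ss = spec.ss_string[nums.index(res)]
        off = SS_SHIFT_OFFSETS[ss].get(nuc, 0.0)
        noise = float(rng.normal(0.0, spec.shift_noise_sd)) if spec.shift_noise_sd else 0.0
        entries[(res, nuc)] = ref + off + noise
    n_keep = int(round(spec.completeness_target * len(entries)))
    keys = sorted(entries)
    keep_idx = rng.choice(len(keys), size=n_keep, replace=False)
    kept = {keys[int(i)]: entries[keys[int(i)]] for i in keep_idx}
    per_res: Dict[int, int] = {}
    for r, _ in kept:
        per_res[r] = per_res.get(r, 0) + 1
    if kept and not any(c >= 2 for c in per_res.values()):
        raise ValueError(
            "completeness_target too low: no residue keeps >= 2 nuclei")
    return ChemicalShiftSet(kept, seq)


# ---------------------------------------------------------------------------
# pairs and corpora
# ---------------------------------------------------------------------------

def make_pair(spec_pred: SyntheticSpec, spec_nmr: SyntheticSpec,
              uniprot_acc: str = "SYN00001", pdb_id: str = "9XXA",
              uniprot_offset: int = 0,
              table: Optional[RandomCoilTable] = None
              ) -> Tuple[PairCandidate, Dict[str, object]]:
    """A predicted-vs-NMR candidate from two specs sharing the same
    sequence and secondary structure.

    The predicted side is a single model whose residues are numbered in the
    reference (UniProt-style) frame, ``uniprot_offset`` above the NMR
    numbering; its per-residue confidence comes from ``spec_pred``'s pLDDT
    profile.  Shifts are simulated from the shared ground truth.  Returns
    the candidate and a ground-truth manifest.
    """
    if (spec_pred.sequence != spec_nmr.sequence
            or spec_pred.ss_string != spec_nmr.ss_string):
        raise ValueError("paired specs must share sequence and ss_string")
    pred_spec = spec_pred
    if spec_pred.plddt_profile is None:
        plddt = [90.0 if ch in "HE" else 50.0 for ch in spec_pred.ss_string]
        pred_spec = SyntheticSpec(**{**spec_pred.__dict__, "plddt_profile": plddt})
    predicted = build_structure(
        SyntheticSpec(**{**pred_spec.__dict__, "n_models": 1,
                         "first_residue": pred_spec.first_residue + uniprot_offset}))
    nmr = build_structure(spec_nmr)
    shifts = simulate_shifts(spec_nmr, table)
    lo, hi = spec_nmr.first_residue, spec_nmr.first_residue + spec_nmr.n_res - 1
    segment = SegmentMapping(
        uniprot_acc=uniprot_acc, pdb_id=pdb_id, chain_id=spec_nmr.chain_id,
        pdb_range=(lo, hi), uniprot_range=(lo + uniprot_offset, hi + uniprot_offset))
    candidate = PairCandidate(
        uniprot_acc=uniprot_acc, nmr_ensemble=nmr, predicted_model=predicted,
        shifts=shifts, segments=[segment],
        well_defined=spec_nmr.ss_segments("HE"))
    completeness_ok = spec_nmr.completeness_target >= 0.75
    expected_filter = []
    if spec_nmr.n_res < 20:
        expected_filter.append("too_short")
    if not completeness_ok:
        expected_filter.append("low_completeness")
    manifest = {
        "uniprot_acc": uniprot_acc,
        "pdb_id": pdb_id,
        "n_res": spec_nmr.n_res,
        "rigid_segments": spec_nmr.ss_segments("HE"),
        "well_defined": spec_nmr.ss_segments("HE"),
        "expected_filter": ";".join(expected_filter) or "pass",
    }
    return candidate, manifest


DEFAULT_DESIGN_COLUMNS = [
    "pair_id", "n_res", "n_helix", "nmr_retention", "pred_retention",
    "noise_sd", "completeness", "n_models", "n_chains", "planted_class",
]


def default_design() -> pd.DataFrame:
    """The default 10-pair study design.

    Three pairs plant a strongly degraded NMR side (predicted much better,
    expected score difference >= +50), one plants the reverse, three are
    near-matched controls, and one each violates the length, completeness
    and single-chain filters.
    """
    rows = [
        # pair_id n_res n_helix nmr_ret pred_ret noise comp n_models n_chains class
        ("af2_best_1", 36, 26, 0.10, 1.00, 0.10, 0.95, 3, 1, "af2_much_better"),
        ("af2_best_2", 40, 30, 0.10, 1.00, 0.15, 0.90, 3, 1, "af2_much_better"),
        ("af2_best_3", 32, 24, 0.10, 1.00, 0.10, 1.00, 3, 1, "af2_much_better"),
        ("nmr_best_1", 36, 26, 1.00, 0.10, 0.10, 0.95, 3, 1, "nmr_much_better"),
        ("neutral_1", 34, 26, 1.00, 1.00, 0.10, 0.95, 4, 1, "neither"),
        ("neutral_2", 38, 30, 0.95, 1.00, 0.15, 0.90, 4, 1, "neither"),
        ("neutral_3", 30, 22, 1.00, 1.00, 0.10, 1.00, 4, 1, "neither"),
        ("too_short", 19, 14, 1.00, 1.00, 0.10, 0.95, 1, 1, "neither"),
        ("low_comp", 32, 24, 1.00, 1.00, 0.10, 0.50, 1, 1, "neither"),
        ("multichain", 32, 24, 1.00, 1.00, 0.10, 0.95, 1, 2, "neither"),
    ]
    return pd.DataFrame(rows, columns=DEFAULT_DESIGN_COLUMNS)


def _design_row_specs(row, seed: int) -> Tuple[SyntheticSpec, SyntheticSpec]:
    n = int(row.n_res)
    n_h = int(row.n_helix)
    n_coil = n - n_h
    tail = n_coil // 2
    head = n_coil - tail
    ss = "C" * head + "H" * n_h + "C" * tail
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ADEFIKLMQRSTVWY"), size=n))
    common = dict(ss_string=ss, sequence=seq, seed=seed)
    nmr_ret = float(row.nmr_retention)
    n_models = int(row.n_models)
    if n_models > 1:
        retention = [max(0.0, min(1.0, nmr_ret + d))
                     for d in np.linspace(-0.1, 0.1, n_models)]
    else:
        retention = [nmr_ret]
    spec_nmr = SyntheticSpec(n_models=n_models,
                             shift_noise_sd=float(row.noise_sd),
                             completeness_target=float(row.completeness),
                             hbond_retention=retention,
                             coil_dispersion=0.5, **common)
    spec_pred = SyntheticSpec(n_models=1, hbond_retention=float(row.pred_retention),
                              coil_dispersion=0.0, **common)
    return spec_pred, spec_nmr


def build_pair_from_design(row, seed: int) -> Tuple[PairCandidate, Dict[str, object]]:
    spec_pred, spec_nmr = _design_row_specs(row, seed)
    # predicted-model confidence tracks the planted prediction quality:
    # a degraded predicted side carries lower pLDDT in its structured core
    rng = np.random.default_rng(seed + 7)
    core = 55.0 + 40.0 * float(row.pred_retention)
    plddt = [float(np.clip((core if ch in "HE" else 45.0)
                           + rng.normal(0.0, 3.0), 0.0, 100.0))
             for ch in spec_pred.ss_string]
    spec_pred = SyntheticSpec(**{**spec_pred.__dict__, "plddt_profile": plddt})
    acc = f"SYN{abs(hash(row.pair_id)) % 90000 + 10000}"
    pdb_id = f"9{str(row.pair_id)[-3:].upper():0>3s}"[:4]
    cand, manifest = make_pair(spec_pred, spec_nmr, uniprot_acc=str(row.pair_id),
                               pdb_id=pdb_id, uniprot_offset=100)
    manifest["planted_class"] = str(row.planted_class)
    if int(row.n_chains) > 1:
        cand = _add_decoy_chain(cand)
        manifest["expected_filter"] = "multichain"
    return cand, manifest


def _add_decoy_chain(cand: PairCandidate) -> PairCandidate:
    """Append a short translated copy of the chain as chain B (makes the
    NMR entry multi-chain for filter testing)."""
    models = []
    for m in cand.nmr_ensemble.models:
        extra = []
        for a in m[:40]:
            b = a.copy()
            b.chain_id = "B"
            b.coords = a.coords + np.array([60.0, 0.0, 0.0])
            extra.append(b)
        models.append(list(m) + extra)
    return PairCandidate(
        uniprot_acc=cand.uniprot_acc,
        nmr_ensemble=StructureEnsemble(models, cand.nmr_ensemble.source_id),
        predicted_model=cand.predicted_model, shifts=cand.shifts,
        segments=cand.segments, well_defined=cand.well_defined)


def build_corpus(out_dir, design: Optional[pd.DataFrame] = None,
                 seed: int = 0) -> pd.DataFrame:
    """Write a fixture corpus (PDB + NMR-STAR + mapping TSV + manifest) and
    return the manifest table.  Deterministic under (design, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = default_design() if design is None else design
    mappings: List[SegmentMapping] = []
    manifest_rows = []
    seen = set()
    for i, row in enumerate(design.itertuples(index=False)):
        pid = str(row.pair_id)
        if pid in seen:
            raise ValueError(f"duplicate pair id {pid}")
        seen.add(pid)
        cand, manifest = build_pair_from_design(row, seed=seed * 1000 + i)
        nmr_path = out_dir / f"nmr_{pid}.pdb"
        pred_path = out_dir / f"pred_{pid}.pdb"
        shift_path = out_dir / f"shifts_{pid}.str"
        structio.write_structure(cand.nmr_ensemble, nmr_path)
        structio.write_structure(cand.predicted_model, pred_path)
        structio.write_shifts(cand.shifts, shift_path, entry_id=pid)
        mappings.extend(cand.segments)
        manifest_rows.append({
            **{k: (str(v) if isinstance(v, list) else v) for k, v in manifest.items()},
            "nmr_file": nmr_path.name, "pred_file": pred_path.name,
            "shift_file": shift_path.name,
            "well_defined": ";".join(f"{a}-{b}" for a, b in manifest["well_defined"]),
            "rigid_segments": ";".join(f"{a}-{b}" for a, b in manifest["rigid_segments"]),
        })
    structio.write_segment_mappings(mappings, out_dir / "mapping.tsv")
    manifest_df = pd.DataFrame(manifest_rows)
    manifest_df.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest_df


def build_reference_distribution(seed: int = 2024, n_structures: int = 60):
    """A reference distribution of (rho, rmsd) values from a varied
    synthetic corpus: sizes 28-52 residues, helix content 40-75 %,
    hydrogen-bond retention 0.2-1.0, shift noise 0-0.4 ppm, including a
    fraction of deliberately mismatched shift assignments so the reference
    spans poor as well as good structures.

    The packaged default reference table is the frozen output of this
    function; regenerate with ``ReferenceDistribution.to_table``.
    """
    from .rci import profile_from_shifts
    from .rigidity import structure_profile
    from .scoring import ReferenceDistribution, compare_profiles

    rng = np.random.default_rng(seed)
    rhos, rmsds = [], []
    for i in range(n_structures):
        n = int(rng.integers(28, 53))
        n_h = int(round(n * rng.uniform(0.4, 0.75)))
        head = (n - n_h) // 2
        ss = "C" * head + "H" * n_h + "C" * (n - n_h - head)
        seq = "".join(rng.choice(list("ADEFIKLMQRSTVWY"), size=n))
        retention = float(rng.uniform(0.2, 1.0))
        noise = float(rng.uniform(0.0, 0.4))
        spec = SyntheticSpec(ss_string=ss, sequence=seq, n_models=1,
                             shift_noise_sd=noise, hbond_retention=retention,
                             seed=int(rng.integers(0, 2 ** 31)))
        ens = build_structure(spec)
        shift_spec = spec
        if i % 5 == 4:  # mismatched assignment: shifts say the mirror image
            flipped = "".join("C" if ch == "H" else "H" for ch in ss)
            shift_spec = SyntheticSpec(**{**spec.__dict__, "ss_string": flipped})
        shifts = simulate_shifts(shift_spec)
        sp = profile_from_shifts(shifts, do_rereference=False)
        stp = structure_profile(ens.models[0])
        rho, rmsd, _ = compare_profiles(sp, stp)
        rhos.append(rho)
        rmsds.append(rmsd)
    return ReferenceDistribution(
        rhos, rmsds,
        provenance=(f"synthetic corpus, {n_structures} structures, seed {seed}; "
                    "see flexscore.synthdata.build_reference_distribution"))


def build_corpus_candidates(design: Optional[pd.DataFrame] = None, seed: int = 0
                            ) -> Tuple[List[PairCandidate], pd.DataFrame]:
    """In-memory corpus (same pairs as :func:`build_corpus`, no files)."""
    design = default_design() if design is None else design
    cands, rows = [], []
    for i, row in enumerate(design.itertuples(index=False)):
        cand, manifest = build_pair_from_design(row, seed=seed * 1000 + i)
        manifest["planted_class"] = str(row.planted_class)
        cands.append(cand)
        rows.append(manifest)
    return cands, pd.DataFrame(rows)
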