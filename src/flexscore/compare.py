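"""The predicted-vs-NMR comparison pipeline.

Pairs a predicted single-model structure with a deposited NMR ensemble via
segment mappings, applies the study filters (single chain, shift
completeness >= 75 %, length >= 20 residues), scores both sides against the
same backbone shifts, and computes the study-level summaries: mean score
differences (ensemble-mean and best-model), a secondary-structure
breakdown, a significance partition at a +/-50 score threshold, and the
correlation between the predicted model's mean confidence (pLDDT) and its
accuracy score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import rci as rci_mod
from .rigidity import build_network, pebble_game, flexibility_index
from .scoring import (
    AnsurrResult,
    ReferenceDistribution,
    aggregate_ensemble,
    score_model,
)
from .structio import place_backbone_amide_hydrogens
from .types import (
    BACKBONE_NUCLEI,
    FlexibilityProfile,
    Model,
    PairCandidate,
    StructureEnsemble,
)

COMPLETENESS_THRESHOLD = 0.75   # inclusive
MIN_RESIDUES = 20               # inclusive
SIGNIFICANCE_THRESHOLD = 50.0   # inclusive, on the ensemble-mean difference


@dataclass
class PipelineOptions:
    energy_cutoff: float = -1.0
    include_ligands: bool = False
    include_tethers: bool = True
    rereference: bool = True
    nuclei: Tuple[str, ...] = BACKBONE_NUCLEI
    rci_options: Optional[rci_mod.RciOptions] = None
    reference: Optional[ReferenceDistribution] = None
    significance_threshold: float = SIGNIFICANCE_THRESHOLD
    # ss_class cutoffs (fractions of classified residues)
    alpha_min_helix: float = 0.15
    beta_min_strand: float = 0.15
    mixed_min_each: float = 0.05

    def get_reference(self) -> ReferenceDistribution:
        if self.reference is None:
            self.reference = ReferenceDistribution.default()
        return self.reference


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_candidate(c: PairCandidate,
                     nuclei: Iterable[str] = BACKBONE_NUCLEI,
                     ) -> Tuple[bool, Set[str]]:
    """Study filters; returns (passed, reason codes).  Reasons are
    independent of the order of checks: all are evaluated."""
    reasons: Set[str] = set()
    if len(c.nmr_ensemble.chain_ids) > 1:
        reasons.add("multichain")
    chain = c.chain_id if c.chain_id in c.nmr_ensemble.chain_ids else None
    seq = c.nmr_ensemble.seq(chain)
    mapped: Set[int] = set()
    for s in c.segments:
        mapped.update(r for r in seq if s.pdb_range[0] <= r <= s.pdb_range[1])
    if len(mapped) < MIN_RESIDUES:
        reasons.add("too_short")
    region_seq = {r: seq[r] for r in mapped} or seq
    comp = rci_mod.completeness(c.shifts, region_seq, nuclei)
    if comp < COMPLETENESS_THRESHOLD:
        reasons.add("low_completeness")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# secondary structure (Kabsch-Sander style)
# ---------------------------------------------------------------------------

_KS_Q = 332.0 * 0.42 * 0.20  # kcal/mol * A, electrostatic H-bond model
_KS_CUTOFF = -0.5            # kcal/mol


def _ks_hbonds(model: Model) -> Set[Tuple[int, int]]:
    """(donor_residue, acceptor_residue) pairs with Kabsch-Sander energy
    below the cutoff.  Donor = backbone N-H, acceptor = backbone C=O."""
    bb: Dict[int, Dict[str, np.ndarray]] = {}
    for a in model:
        if a.hetero:
            continue
        if a.name in ("N", "CA", "C", "O", "H"):
            bb.setdefault(a.res_seq, {})[a.name] = a.coords
    out: Set[Tuple[int, int]] = set()
    residues = sorted(bb)
    for i in residues:  # donor
        d = bb[i]
        if "N" not in d or "H" not in d:
            continue
        for j in residues:  # acceptor
            if abs(i - j) < 2:
                continue
            acc = bb[j]
            if "C" not in acc or "O" not in acc:
                continue
            r_on = np.linalg.norm(acc["O"] - d["N"])
            if r_on > 5.2:
                continue
            r_ch = np.linalg.norm(acc["C"] - d["H"])
            r_oh = np.linalg.norm(acc["O"] - d["H"])
            r_cn = np.linalg.norm(acc["C"] - d["N"])
            e = _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _KS_CUTOFF:
                out.add((i, j))
    return out


def classify_ss(model: Model, opts: Optional[PipelineOptions] = None
                ) -> Tuple[Dict[int, str], Optional[str]]:
    """Per-residue secondary structure in {H, E, C} plus the protein-level
    class in {alpha, beta, mixed, None}.

    Helices come from consecutive i -> i+4 turn patterns, strands from
    (anti)parallel bridge patterns, following the classic backbone-amide
    electrostatic criterion.
    """
    opts = opts or PipelineOptions()
    if not any(a.name == "O" for a in model if not a.hetero):
        raise ValueError("backbone carbonyl O atoms required for SS assignment")
    hb = _ks_hbonds(model)
    residues = sorted({a.res_seq for a in model
                       if not a.hetero and a.name == "CA"})
    rset = set(residues)

    def hbond(don: int, acc: int) -> bool:
        return (don, acc) in hb

    # n-turn at i: residue i accepts an H-bond from residue i+4
    turn = {i for i in residues if hbond(i + 4, i)}
    ss: Dict[int, str] = {i: "C" for i in residues}
    for i in turn:
        if i - 1 in turn:
            for j in range(i + 1, i + 5):
                if j in rset:
                    ss[j] = "H"
    # bridges
    for i in residues:
        for j in residues:
            if j < i + 3:
                continue
            para = ((hbond(i + 1, j) and hbond(j, i - 1))
                    or (hbond(j + 1, i) and hbond(i, j - 1)))
            anti = ((hbond(i, j) and hbond(j, i))
                    or (hbond(i - 1, j + 1) and hbond(j - 1, i + 1)))
            if para or anti:
                if ss.get(i) != "H":
                    ss[i] = "E"
                if ss.get(j) != "H":
                    ss[j] = "E"
    n = len(residues)
    fh = sum(1 for v in ss.values() if v == "H") / n if n else 0.0
    fe = sum(1 for v in ss.values() if v == "E") / n if n else 0.0
    if fh >= opts.alpha_min_helix and fe < opts.mixed_min_each:
        ss_class: Optional[str] = "alpha"
    elif fe >= opts.beta_min_strand and fh < opts.mixed_min_each:
        ss_class = "beta"
    elif fh >= opts.mixed_min_each and fe >= opts.mixed_min_each:
        ss_class = "mixed"
    else:
        ss_class = None
    return ss, ss_class


# ---------------------------------------------------------------------------
# pLDDT
# ---------------------------------------------------------------------------

def mean_plddt(model: Model,
               regions: Optional[Sequence[Tuple[int, int]]] = None) -> float:
    """Mean per-residue confidence (one value per residue, from the CA
    atom), optionally restricted to inclusive residue intervals."""
    values: Dict[int, float] = {}
    for a in model:
        if a.name == "CA" and not a.hetero:
            values[a.res_seq] = a.bfactor
    if regions is not None:
        keep = {r for lo, hi in regions for r in values if lo <= r <= hi}
        if not keep:
            raise ValueError("regions do not intersect the model's residues")
        values = {r: values[r] for r in keep}
    if not values:
        raise ValueError("no CA atoms with confidence values")
    return float(np.mean(list(values.values())))


# ---------------------------------------------------------------------------
# pair scoring
# ---------------------------------------------------------------------------

def shift_profile(c: PairCandidate, opts: PipelineOptions) -> FlexibilityProfile:
    table = rci_mod.RandomCoilTable.default()
    return rci_mod.profile_from_shifts(
        c.shifts, table=table, opts=opts.rci_options,
        do_rereference=opts.rereference)


def _model_profile(model: Model, opts: PipelineOptions) -> FlexibilityProfile:
    model = place_backbone_amide_hydrogens(model)
    net = build_network(model, energy_cutoff=opts.energy_cutoff,
                        include_ligands=opts.include_ligands,
                        include_tethers=opts.include_tethers)
    dec = pebble_game(net)
    return flexibility_index(net, dec)


@dataclass
class ComparisonRecord:
    pair_id: str
    nmr_mean_score: float
    nmr_best_score: float
    af2_score: float
    ss_class: Optional[str]
    mean_plddt_all: float
    mean_plddt_well_defined: Optional[float]
    n_models: int
    n_residues: int
    significance: str = "neither"

    @property
    def diff_mean(self) -> float:
        return self.af2_score - self.nmr_mean_score

    @property
    def diff_best(self) -> float:
        return self.af2_score - self.nmr_best_score


def score_pair(c: PairCandidate, opts: Optional[PipelineOptions] = None
               ) -> ComparisonRecord:
    """Score one candidate.

    NMR side: the full deposited chain, every model, aggregated as the
    ensemble mean and the best-scoring model.  Predicted side: each mapped
    segment is extracted from the predicted model (reference numbering),
    renumbered into the deposited frame, scored against the same shifts,
    and the per-segment scores averaged.
    """
    opts = opts or PipelineOptions()
    ref = opts.get_reference()
    try:
        sp = shift_profile(c, opts)
        chain = (c.chain_id if c.chain_id in c.nmr_ensemble.chain_ids
                 else c.nmr_ensemble.chain_ids[0])
        nmr = (c.nmr_ensemble.select_chain(chain)
               if len(c.nmr_ensemble.chain_ids) > 1 else c.nmr_ensemble)
        nmr_results = []
        for m, model in enumerate(nmr.models):
            prof = _model_profile(model, opts)
            nmr_results.append(score_model(sp, prof, ref, model_index=m))
        nmr_mean = aggregate_ensemble(nmr_results, "mean")
        nmr_best = aggregate_ensemble(nmr_results, "best")
        seg_scores = []
        for seg in c.segments:
            # one flanking residue on each side (when present) is kept as
            # mechanical context so the cut ends are not artificially floppy;
            # scores still compare only residues with shifts
            lo, hi = seg.uniprot_range
            region = c.predicted_model.extract_region([(lo - 1, hi + 1)])
            region = region.renumber(-seg.offset)
            prof = _model_profile(region.models[0], opts)
            seg_scores.append(score_model(sp, prof, ref).ansurr_score)
        af2 = float(np.mean(seg_scores))
        _, ss_class = classify_ss(c.predicted_model.models[0], opts)
        plddt_all = mean_plddt(c.predicted_model.models[0])
        plddt_wd = None
        if c.well_defined:
            wd_pred = [(lo + c.segments[0].offset, hi + c.segments[0].offset)
                       for lo, hi in c.well_defined]
            try:
                plddt_wd = mean_plddt(c.predicted_model.models[0], wd_pred)
            except ValueError:
                plddt_wd = None
        return ComparisonRecord(
            pair_id=c.uniprot_acc,
            nmr_mean_score=nmr_mean.ansurr_score,
            nmr_best_score=nmr_best.ansurr_score,
            af2_score=af2, ss_class=ss_class,
            mean_plddt_all=plddt_all, mean_plddt_well_defined=plddt_wd,
            n_models=len(nmr.models), n_residues=len(nmr.seq()),
        )
    except Exception as exc:
        raise RuntimeError(f"scoring failed for pair {c.uniprot_acc}: {exc}") from exc


def score_accession(candidates: Sequence[PairCandidate],
                    opts: Optional[PipelineOptions] = None) -> ComparisonRecord:
    """Two-level averaging for an accession mapped to several deposited
    entries: per-entry scores first, then the mean of entry scores on both
    sides (ensemble-mean and best-model alike)."""
    if not candidates:
        raise ValueError("no candidates for accession")
    records = [score_pair(c, opts) for c in candidates]
    if len(records) == 1:
        return records[0]
    first = records[0]
    return ComparisonRecord(
        pair_id=candidates[0].uniprot_acc,
        nmr_mean_score=float(np.mean([r.nmr_mean_score for r in records])),
        nmr_best_score=float(np.mean([r.nmr_best_score for r in records])),
        af2_score=float(np.mean([r.af2_score for r in records])),
        ss_class=first.ss_class,
        mean_plddt_all=first.mean_plddt_all,
        mean_plddt_well_defined=first.mean_plddt_well_defined,
        n_models=sum(r.n_models for r in records),
        n_residues=max(r.n_residues for r in records),
    )


# ---------------------------------------------------------------------------
# study summaries
# ---------------------------------------------------------------------------

def partition_significance(records: Sequence[ComparisonRecord],
                           threshold: float = SIGNIFICANCE_THRESHOLD
                           ) -> Dict[str, int]:
    """Inclusive partition on the ensemble-mean difference."""
    counts = {"af2_much_better": 0, "nmr_much_better": 0, "neither": 0}
    for r in records:
        if r.diff_mean >= threshold:
            r.significance = "af2_much_better"
        elif r.diff_mean <= -threshold:
            r.significance = "nmr_much_better"
        else:
            r.significance = "neither"
        counts[r.significance] += 1
    return counts


def correlate_plddt_ansurr(records: Sequence[ComparisonRecord],
                           variant: str = "all") -> Tuple[float, float]:
    """Pearson r (and two-tailed p from the t transform, n-2 df) between
    mean pLDDT and the predicted model's accuracy score."""
    if variant == "all":
        xs = [r.mean_plddt_all for r in records]
    elif variant == "well_defined":
        xs = [r.mean_plddt_well_defined for r in records
              if r.mean_plddt_well_defined is not None]
        records = [r for r in records if r.mean_plddt_well_defined is not None]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    ys = [r.af2_score for r in records]
    if len(xs) < 3:
        raise ValueError("need >= 3 records for a correlation")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StudySummary:
    n_pairs: int
    mean_diff_ensemble: float
    mean_diff_best: float
    mean_diff_by_ss: Dict[str, float]
    significance_counts: Dict[str, int]
    significance_fractions: Dict[str, float]
    pearson_all: Optional[Tuple[float, float]]
    pearson_well_defined: Optional[Tuple[float, float]]
    diff_histogram: Dict[str, List[float]] = field(default_factory=dict)


def summarize(records: Sequence[ComparisonRecord],
              threshold: float = SIGNIFICANCE_THRESHOLD) -> StudySummary:
    """All study-level quantities from a set of comparison records."""
    if not records:
        raise ValueError("no records to summarise")
    diffs = np.array([r.diff_mean for r in records])
    diffs_best = np.array([r.diff_best for r in records])
    counts = partition_significance(records, threshold)
    n = len(records)
    by_ss: Dict[str, float] = {}
    for cls in ("alpha", "beta", "mixed"):
        sel = [r.diff_mean for r in records if r.ss_class == cls]
        if sel:
            by_ss[cls] = float(np.mean(sel))
    try:
        p_all = correlate_plddt_ansurr(records, "all")
    except ValueError:
        p_all = None
    try:
        p_wd = correlate_plddt_ansurr(records, "well_defined")
    except ValueError:
        p_wd = None
    # histogram of differences, fixed bin width of 10 score units
    lo = math.floor(diffs.min() / 10.0) * 10.0
    hi = math.ceil(diffs.max() / 10.0) * 10.0 + 10.0
    edges = np.arange(lo, hi + 1e-9, 10.0)
    hist, _ = np.histogram(diffs, bins=edges)
    return StudySummary(
        n_pairs=n,
        mean_diff_ensemble=float(diffs.mean()),
        mean_diff_best=float(diffs_best.mean()),
        mean_diff_by_ss=by_ss,
        significance_counts=counts,
        significance_fractions={k: v / n for k, v in counts.items()},
        pearson_all=p_all,
        pearson_well_defined=p_wd,
        diff_histogram={"edges": edges.tolist(), "counts": hist.tolist()},
    )


def run_study(candidates: Sequence[PairCandidate],
              opts: Optional[PipelineOptions] = None,
              ) -> Tuple[pd.DataFrame, List[ComparisonRecord], StudySummary]:
    """Filter, score and summarise a corpus of candidates.

    Candidates sharing an accession are combined by two-level averaging.
    Every candidate is scored (filter status is recorded alongside) so that
    planted filter-failure fixtures still contribute a record.
    """
    opts = opts or PipelineOptions()
    filter_rows = []
    groups: Dict[str, List[PairCandidate]] = {}
    for c in candidates:
        passed, reasons = filter_candidate(c, opts.nuclei)
        filter_rows.append({"pair_id": c.uniprot_acc, "passed": passed,
                            "reasons": ";".join(sorted(reasons))})
        groups.setdefault(c.uniprot_acc, []).append(c)
    records = [score_accession(cands, opts) for cands in groups.values()]
    summary = summarize(records, opts.significance_threshold)
    return pd.DataFrame(filter_rows), records, summary
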