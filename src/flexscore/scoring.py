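"""Compare the two flexibility profiles and produce correlation, RMSD and
combined accuracy scores.

The shift-derived and structure-derived profiles are compared over the
residues defined in both by (a) the Spearman rank correlation rho and (b)
the root-mean-square difference.  Each raw value is converted to a centile
against a reference distribution (mid-rank tie handling), giving a
correlation score and an RMSD score in [0, 100]; their sum is the combined
accuracy score in [0, 200].  Centile scores are only comparable within a
stated reference, so the reference's provenance is carried through to every
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import FlexibilityProfile


@dataclass
class AnsurrResult:
    """Scores for one model (or one ensemble aggregate)."""

    rho: float
    rmsd: float
    corr_score: float
    rmsd_score: float
    ansurr_score: float
    n_residues_compared: int
    model_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.rho <= 1.0 + 1e-9):
            raise ValueError(f"rho {self.rho} outside [-1, 1]")
        for name in ("corr_score", "rmsd_score"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} {v} outside [0, 100]")
        if abs(self.ansurr_score - (self.corr_score + self.rmsd_score)) > 1e-9:
            raise ValueError("ansurr_score must equal corr_score + rmsd_score")


class ReferenceDistribution:
    """Sorted reference values of rho and RMSD used for centile scoring."""

    def __init__(self, rho_ref: Sequence[float], rmsd_ref: Sequence[float],
                 provenance: str = "unspecified"):
        self.rho_ref = sorted(float(v) for v in rho_ref)
        self.rmsd_ref = sorted(float(v) for v in rmsd_ref)
        self.provenance = provenance
        if len(self.rho_ref) < 10 or len(self.rmsd_ref) < 10:
            raise ValueError("reference distributions need >= 10 values")

    @classmethod
    def from_table(cls, path) -> "ReferenceDistribution":
        df = pd.read_csv(path, sep="\t")
        prov = "user table"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# provenance:"):
                prov = first.split(":", 1)[1].strip()
                df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df["rho"].dropna(), df["rmsd"].dropna(), provenance=prov)

    @classmethod
    def default(cls) -> "ReferenceDistribution":
        """Packaged default built from a synthetic fixture corpus (see the
        file header for generation parameters)."""
        ref = resources.files("flexscore.data").joinpath(
            "reference_synthetic.tsv")
        with resources.as_file(ref) as path:
            return cls.from_table(path)

    def to_table(self, path) -> None:
        n = max(len(self.rho_ref), len(self.rmsd_ref))
        rho = list(self.rho_ref) + [np.nan] * (n - len(self.rho_ref))
        rmsd = list(self.rmsd_ref) + [np.nan] * (n - len(self.rmsd_ref))
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            pd.DataFrame({"rho": rho, "rmsd": rmsd}).to_csv(
                fh, sep="\t", index=False)


def compare_profiles(shift_prof: FlexibilityProfile,
                     struct_prof: FlexibilityProfile,
                     min_overlap: int = 5) -> Tuple[float, float, int]:
    """(Spearman rho, RMSD, n) over the residues defined in both profiles."""
    common = sorted(set(shift_prof.defined()) & set(struct_prof.defined()))
    n = len(common)
    if n < min_overlap:
        raise ValueError(
            f"only {n} residues defined in both profiles (need >= {min_overlap})")
    a = np.array([shift_prof.values[r] for r in common])
    b = np.array([struct_prof.values[r] for r in common])
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        rho = 0.0  # rank correlation undefined for a constant profile
    else:
        rho = float(stats.spearmanr(a, b).statistic)
    rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
    return rho, rmsd, n


def centile_scores(rho: float, rmsd: float, ref: ReferenceDistribution
                   ) -> Tuple[float, float]:
    """Centiles of rho (higher better) and RMSD (lower better) against the
    reference, mid-rank ties, clamped to [0, 100]."""
    if not ref.rho_ref or not ref.rmsd_ref:
        raise ValueError("empty reference distribution")

    def centile(value: float, values: List[float], greater: bool) -> float:
        arr = np.asarray(values)
        if greater:
            beaten = int(np.sum(arr > value))
        else:
            beaten = int(np.sum(arr < value))
        ties = int(np.sum(arr == value))
        return float(np.clip(100.0 * (beaten + 0.5 * ties) / len(arr), 0.0, 100.0))

    return (centile(rho, ref.rho_ref, greater=False),
            centile(rmsd, ref.rmsd_ref, greater=True))


def ansurr_score(corr_score: float, rmsd_score: float) -> float:
    """Sum of the two centile scores, range [0, 200]."""
    for name, v in (("corr_score", corr_score), ("rmsd_score", rmsd_score)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} {v} outside [0, 100]")
    return corr_score + rmsd_score


def score_model(shift_prof: FlexibilityProfile, struct_prof: FlexibilityProfile,
                ref: Optional[ReferenceDistribution] = None,
                model_index: Optional[int] = None) -> AnsurrResult:
    ref = ref or ReferenceDistribution.default()
    rho, rmsd, n = compare_profiles(shift_prof, struct_prof)
    cs, rs = centile_scores(rho, rmsd, ref)
    return AnsurrResult(rho=rho, rmsd=rmsd, corr_score=cs, rmsd_score=rs,
                        ansurr_score=ansurr_score(cs, rs),
                        n_residues_compared=n, model_index=model_index)


def aggregate_ensemble(results: Sequence[AnsurrResult], mode: str = "mean"
                       ) -> AnsurrResult:
    """Ensemble aggregate: component-wise mean, or the best-scoring model
    (ties broken by lowest model index)."""
    if not results:
        raise ValueError("cannot aggregate an empty result list")
    if mode == "mean":
        cs = float(np.mean([r.corr_score for r in results]))
        rs = float(np.mean([r.rmsd_score for r in results]))
        return AnsurrResult(
            rho=float(np.mean([r.rho for r in results])),
            rmsd=float(np.mean([r.rmsd for r in results])),
            corr_score=cs, rmsd_score=rs, ansurr_score=cs + rs,
            n_residues_compared=int(round(np.mean(
                [r.n_residues_compared for r in results]))),
        )
    if mode == "best":
        order = sorted(
            range(len(results)),
            key=lambda i: (-results[i].ansurr_score,
                           results[i].model_index if results[i].model_index
                           is not None else i))
        return results[order[0]]
    raise ValueError(f"unknown aggregation mode {mode!r}")


def results_table(results: Iterable[AnsurrResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "model": r.model_index, "rho": r.rho, "rmsd": r.rmsd,
        "corr_score": r.corr_score, "rmsd_score": r.rmsd_score,
        "ansurr_score": r.ansurr_score, "n_compared": r.n_residues_compared,
    } for r in results])
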