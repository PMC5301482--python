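"""Mismatch-budget calibration: method-1 vs method-2 over a grid of k.

The mapping-based caller (method 1) is re-run with mismatch budgets k
(default 2..10) and each run's site set is scored against the consensus
caller's set (method 2, the assembly-method stand-in, computed once from the
most permissive mapping) with

    sensitivity = |M1 ∩ M2| / |M2|        specificity = |M1 ∩ M2| / |M1|

Too small a k unmaps reads over dense editing clusters (low sensitivity);
the "best combination" is operationalized as the maximal harmonic mean,
ties resolved toward smaller k.  The full grid table is the primary output;
the scalar pick is a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import calling, mapping


@dataclass
class CalibrationResult:
    k: int
    n_method1_sites: int
    n_method2_sites: int
    n_shared: int
    sensitivity: float | None  # None when method-2 set is empty
    specificity: float | None  # None when method-1 set is empty

    @property
    def harmonic_mean(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        if self.sensitivity + self.specificity == 0:
            return 0.0
        return (
            2 * self.sensitivity * self.specificity
            / (self.sensitivity + self.specificity)
        )

    @property
    def degenerate(self) -> bool:
        return self.sensitivity is None or self.specificity is None


def sensitivity_specificity(m1_sites: set, m2_sites: set) -> tuple[float, float]:
    """Exact set-intersection ratios over (position, strand, ref, alt) keys."""
    if not m2_sites:
        raise ValueError("method-2 set empty: sensitivity undefined")
    if not m1_sites:
        raise ValueError("method-1 set empty: specificity undefined")
    shared = len(m1_sites & m2_sites)
    return shared / len(m2_sites), shared / len(m1_sites)


def run_grid(
    reads,
    genome: mapping.Genome,
    k_values=tuple(range(2, 11)),
    caller_params: dict | None = None,
    consensus_c_min: int = 5,
    method: str = "seed",
) -> list[CalibrationResult]:
    """Map/call at every k; score against the consensus set from the max-k map."""
    if not k_values:
        raise ValueError("k_values must be non-empty")
    k_values = sorted(k_values)
    caller_params = dict(caller_params or {})
    reads = list(reads)

    aln_max, _ = mapping.map_reads(reads, genome, max(k_values), method=method)
    pile_max = calling.build_pileup(aln_max, genome)
    m2 = {
        s.key for s in calling.consensus_sites(pile_max, genome, c_min=consensus_c_min)
    }

    results = []
    for k in k_values:
        alns, _ = mapping.map_reads(reads, genome, k, method=method)
        pile = calling.build_pileup(alns, genome)
        m1 = {s.key for s in calling.call_editing_sites(pile, genome, **caller_params)}
        shared = len(m1 & m2)
        results.append(
            CalibrationResult(
                k=k,
                n_method1_sites=len(m1),
                n_method2_sites=len(m2),
                n_shared=shared,
                sensitivity=shared / len(m2) if m2 else None,
                specificity=shared / len(m1) if m1 else None,
            )
        )
    return results


def select_k(results: list[CalibrationResult]) -> int:
    """The k with maximal harmonic-mean sensitivity/specificity (ties: smaller k)."""
    valid = [r for r in results if not r.degenerate]
    if not valid:
        raise ValueError("all calibration rows degenerate: cannot select k")
    best = max(valid, key=lambda r: (r.harmonic_mean, -r.k))
    return best.k


def grid_table(results: list[CalibrationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "k": r.k,
                "n_method1_sites": r.n_method1_sites,
                "n_method2_sites": r.n_method2_sites,
                "n_shared": r.n_shared,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "harmonic_mean": r.harmonic_mean,
            }
            for r in results
        ]
    )
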