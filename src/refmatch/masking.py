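"""Nested masking of good-quality SNPs for the re-imputation benchmark.

Whole SNPs (all individuals of the target) are masked, never sporadic
genotypes. Masks are nested by construction: one seeded permutation of the
GQ markers is drawn and the mask for fraction f is its first round(f * n)
elements, so every SNP masked at a lower fraction is also masked at every
higher fraction. Cross-missingness comparisons downstream therefore use
only the markers of the smallest fraction's mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypePanel

DEFAULT_FRACTIONS = (0.5, 0.7, 1.0)


@dataclass
class MaskPlan:
    """Per-fraction nested sets of masked GQ marker ids."""

    fractions: tuple
    masked_markers: dict  # fraction -> list of marker ids (prefix-nested)
    seed: int

    def mask(self, fraction: float) -> list[str]:
        if fraction not in self.masked_markers:
            raise KeyError(f"fraction {fraction} not in plan "
                           f"{tuple(self.masked_markers)}")
        return self.masked_markers[fraction]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fraction": f, "marker": m}
                for f in self.fractions for m in self.masked_markers[f]]
        return pd.DataFrame(rows)


def build_mask_plan(gq_markers: list[str],
                    fractions=DEFAULT_FRACTIONS, seed: int = 0) -> MaskPlan:
    """One seeded permutation of the GQ markers; mask(f) = first
    round(f * n) elements, so nesting holds by construction."""
    if len(gq_markers) == 0:
        raise ValueError("empty GQ marker set")
    fractions = tuple(fractions)
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fraction {f} outside (0, 1]")
    rng = np.random.default_rng(seed)
    perm = [gq_markers[i] for i in rng.permutation(len(gq_markers))]
    masked = {f: perm[: int(np.floor(f * len(perm) + 0.5))] for f in fractions}
    return MaskPlan(fractions, masked, seed)


def apply_mask(panel: GenotypePanel, plan: MaskPlan, fraction: float
               ) -> tuple[GenotypePanel, pd.DataFrame]:
    """Set the planned markers to missing for every individual.

    Returns (masked copy, truth table). The truth table is a samples x
    masked-markers DataFrame of the original calls, for scoring.
    """
    to_mask = plan.mask(fraction)
    index = {m.id: k for k, m in enumerate(panel.markers)}
    missing_ids = [m for m in to_mask if m not in index]
    if missing_ids:
        raise ValueError(f"markers in plan absent from panel: {missing_ids[:5]}")
    cols = [index[m] for m in to_mask]
    truth = pd.DataFrame(panel.calls[:, cols].copy(), index=list(panel.samples),
                         columns=list(to_mask))
    calls = panel.calls.copy()
    calls[:, cols] = MISSING
    masked = GenotypePanel(panel.population, list(panel.markers),
                           list(panel.samples), calls)
    return masked, truth
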