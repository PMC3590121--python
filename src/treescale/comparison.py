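"""Scoring theoretical scaling models against fitted exponents.

Three closed-form theories predict the scaling exponent ``b`` of each
trait against branch (or basal) diameter:

===========================  =======  ========  =========  =========
Model                        length   AG mass   stem mass  leaf mass
===========================  =======  ========  =========  =========
Metabolic Scaling Theory     2/3      8/3       8/3        2
Geometric Similarity         1        3         3          2
Stress Similarity            1/2      5/2       --         --
===========================  =======  ========  =========  =========

A theory is *supported* by a fitted exponent when its prediction lies
inside the exponent's 95% credible interval.  Support is tallied across
every hierarchical unit — each tree, each species, and the global level
— and the model with the highest inclusion percentage is "best" (ties
reported, never broken).  Predictions are exact rationals and are
compared at full precision against floating CI bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd

from .preprocess import TRAITS
from .sampler import LEVELS, PosteriorSamples, summarize_level

MODELS = ("MST", "GEOM", "STRESS")

_PREDICTIONS: dict[str, dict[str, Fraction | None]] = {
    "MST": {
        "length": Fraction(2, 3),
        "ag_mass": Fraction(8, 3),
        "stem_mass": Fraction(8, 3),
        "leaf_mass": Fraction(2),
    },
    "GEOM": {
        "length": Fraction(1),
        "ag_mass": Fraction(3),
        "stem_mass": Fraction(3),
        "leaf_mass": Fraction(2),
    },
    "STRESS": {
        "length": Fraction(1, 2),
        "ag_mass": Fraction(5, 2),
        "stem_mass": None,
        "leaf_mass": None,
    },
}

#: traits every theory makes a prediction for
COMMON_TRAITS = ("length", "ag_mass")


def theoretical_exponent(model: str, trait: str) -> Fraction | None:
    """Exact predicted exponent, or None where the theory is silent."""
    if model not in _PREDICTIONS:
        raise KeyError(f"unknown scaling model {model!r}")
    if trait not in _PREDICTIONS[model]:
        raise KeyError(f"unknown trait {trait!r}")
    return _PREDICTIONS[model][trait]


def exponent_ci_table(
    samples: PosteriorSamples, traits: tuple[str, ...] = TRAITS
) -> pd.DataFrame:
    """Exponent summaries for every (trait, unit) at all hierarchy levels.

    One row per tree, per species and for the global level, per trait:
    n_trees + n_species + 1 rows per trait.
    """
    frames = []
    for trait in traits:
        for level in ("tree", "species", "global"):
            s = summarize_level(samples, level, trait, kind="b")
            s.insert(0, "level", level)
            s.insert(0, "trait", trait)
            frames.append(s)
    return pd.concat(frames, ignore_index=True)


def ci_inclusion_table(
    ci_table: pd.DataFrame, models: tuple[str, ...] = MODELS
) -> pd.DataFrame:
    """Add per-model inclusion flags to an exponent CI table.

    A flag is True when the model's prediction lies inside
    [q2_5, q97_5]; missing (pd.NA) where the model makes no prediction.
    """
    required = {"trait", "level", "unit", "q2_5", "q97_5"}
    missing = required - set(ci_table.columns)
    if missing:
        raise ValueError(f"CI table missing columns {sorted(missing)}")
    for level in ("tree", "species", "global"):
        if level not in set(ci_table["level"]):
            raise ValueError(f"CI table lacks hierarchy level {level!r}")
    out = ci_table.copy()
    for m in models:
        flags = []
        for _, row in out.iterrows():
            pred = theoretical_exponent(m, row["trait"])
            if pred is None:
                flags.append(pd.NA)
            else:
                flags.append(bool(row["q2_5"] <= float(pred) <= row["q97_5"]))
        out[f"incl_{m}"] = pd.array(flags, dtype="boolean")
    return out


def inclusion_percentage_and_best(
    inclusion_table: pd.DataFrame, models: tuple[str, ...] = MODELS
) -> dict:
    """Inclusion percentages per model and the best-supported model(s).

    Percentages are 100 x included / defined comparisons; cells where a
    theory makes no prediction are excluded from its denominator.  Also
    reported restricted to the traits all theories predict.  Ties for
    best are returned as a tuple, not broken.
    """
    if len(inclusion_table) == 0:
        raise ValueError("empty inclusion table")
    overall: dict[str, float] = {}
    common: dict[str, float] = {}
    for m in models:
        col = inclusion_table[f"incl_{m}"]
        defined = col.notna()
        overall[m] = 100.0 * col[defined].sum() / max(int(defined.sum()), 1)
        sub = inclusion_table["trait"].isin(COMMON_TRAITS) & defined
        common[m] = 100.0 * col[sub].sum() / max(int(sub.sum()), 1)
    top = max(overall.values())
    best = tuple(m for m in models if overall[m] == top)
    return {"overall": overall, "common_traits": common, "best": best}


def contrast_probability(
    samples: PosteriorSamples, trait: str, species_a: str, species_b: str
) -> float:
    """Posterior probability that species_a's exponent exceeds species_b's."""
    labels = list(samples.species_labels)
    for sp in (species_a, species_b):
        if sp not in labels:
            raise KeyError(f"unknown species {sp!r}")
    draws = samples.draws("species", trait, "b")  # (C, K, S)
    da = draws[..., labels.index(species_a)].ravel()
    db = draws[..., labels.index(species_b)].ravel()
    return float(np.mean(da - db > 0.0))


@dataclass
class ComparisonReport:
    """CI-inclusion table, per-model percentages and species contrasts."""

    inclusion_table: pd.DataFrame
    percentages: dict
    best: tuple
    contrasts: pd.DataFrame

    def to_text(self) -> str:
        lines = ["Theoretical scaling-model comparison", ""]
        lines.append(
            "Inclusion of theoretical predictions in 95% credible intervals"
        )
        for m in MODELS:
            lines.append(
                f"  {m:7s} overall {self.percentages['overall'][m]:5.1f}%   "
                f"length+AG mass {self.percentages['common_traits'][m]:5.1f}%"
            )
        lines.append(f"Best-supported model(s): {', '.join(self.best)}")
        lines.append("")
        lines.append("Species exponent contrasts P(b_a - b_b > 0):")
        for _, r in self.contrasts.iterrows():
            lines.append(
                f"  {r['trait']:10s} {r['species_a']} - {r['species_b']}: "
                f"{r['probability']:.3f}"
            )
        return "\n".join(lines)


def make_report(
    samples: PosteriorSamples, traits: tuple[str, ...] = TRAITS
) -> ComparisonReport:
    """Full model-comparison report from fitted posterior samples."""
    table = ci_inclusion_table(exponent_ci_table(samples, traits))
    pct = inclusion_percentage_and_best(table)
    rows = []
    for trait in traits:
        for a, b in combinations(samples.species_labels, 2):
            rows.append(
                {
                    "trait": trait,
                    "species_a": a,
                    "species_b": b,
                    "probability": contrast_probability(samples, trait, a, b),
                }
            )
    contrasts = pd.DataFrame(rows)
    return ComparisonReport(
        inclusion_table=table,
        percentages={k: pct[k] for k in ("overall", "common_traits")},
        best=pct["best"],
        contrasts=contrasts,
    )
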