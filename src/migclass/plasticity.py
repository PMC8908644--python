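"""Inter-annual behavioural plasticity and between-category comparisons.

Plasticity of an individual with yearly behavioural classifications is

    P = dC_years / (C_years - 1)

where C_years is the number of classified years and dC_years the number of
switches between sequential years: P = 0 means the behaviour never
switched, P = 1 that it switched every year.  P is computed under a
four-category scheme (mixed migrants merged into migrants) and under the
binary migrant/resident scheme.

Seasonal-range overlap (IO) is compared between behavioural categories
with a Kruskal-Wallis omnibus test; pairwise Mann-Whitney U tests follow
only when the omnibus is significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

PLANAR_VOCAB = {"migrant", "mixed_migrant", "resident", "disperser", "nomad"}
BINARY_VOCAB = {"migrant", "resident"}


class SequenceTooShortError(ValueError):
    """Plasticity needs at least two classified years."""


@dataclass
class PlasticityRecord:
    animal_id: str
    scheme: str  # 'merged4' | 'binary'
    yearly_categories: list[str]
    n_switches: int
    p: float


@dataclass
class GroupComparison:
    grouping: str
    groups: dict[str, list[float]]
    h_statistic: float
    p_value: float
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)


def merge_categories(yearly: Sequence[str], scheme: str = "merged4") -> list[str]:
    """Map yearly labels into the scheme's vocabulary.

    ``merged4`` folds mixed_migrant into migrant, keeping {migrant,
    resident, disperser, nomad}; ``binary`` requires labels already from a
    binary migrant/resident classification.
    """
    if scheme == "merged4":
        out = []
        for c in yearly:
            if c not in PLANAR_VOCAB:
                raise ValueError(f"unknown category label {c!r}")
            out.append("migrant" if c == "mixed_migrant" else c)
        return out
    if scheme == "binary":
        bad = [c for c in yearly if c not in BINARY_VOCAB]
        if bad:
            raise ValueError(
                f"binary plasticity requires binary classifications; got {bad}")
        return list(yearly)
    raise ValueError(f"unknown scheme {scheme!r}")


def plasticity(yearly: Sequence[str], animal_id: str = "",
               scheme: str = "merged4") -> PlasticityRecord:
    """P = (number of sequential switches) / (years - 1)."""
    yearly = list(yearly)
    if len(yearly) < 2:
        raise SequenceTooShortError(
            f"{animal_id or 'animal'}: plasticity needs >= 2 classified years")
    switches = sum(a != b for a, b in zip(yearly, yearly[1:]))
    return PlasticityRecord(animal_id, scheme, yearly, switches,
                            switches / (len(yearly) - 1))


def compare_overlap_by_category(io_by_category: dict[str, Sequence[float]],
                                alpha: float = 0.05,
                                grouping: str = "nsd_category",
                                bonferroni: bool = False) -> GroupComparison:
    """Kruskal-Wallis omnibus (tie-corrected) on IO across categories, with
    two-sided Mann-Whitney U pairwise tests gated on omnibus p < alpha.

    Empty groups are dropped with a warning.  By default no
    multiple-testing correction is applied to the pairwise tests (the
    omnibus is the gatekeeper); ``bonferroni=True`` multiplies pairwise
    p-values by the number of pairs (capped at 1).
    """
    groups = {}
    for name, vals in io_by_category.items():
        vals = [float(v) for v in vals]
        if not vals:
            warnings.warn(f"group {name!r} is empty; dropped")
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    names = sorted(groups)
    h, p = stats.kruskal(*[groups[n] for n in names])
    pairwise = []
    if p < alpha:
        n_pairs = len(names) * (len(names) - 1) // 2
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                u, pu = stats.mannwhitneyu(groups[names[i]], groups[names[j]],
                                           alternative="two-sided")
                if bonferroni:
                    pu = min(1.0, pu * n_pairs)
                pairwise.append((names[i], names[j], float(u), float(pu)))
    return GroupComparison(grouping, groups, float(h), float(p), pairwise)
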