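"""Actuarial (Jak/Bondi) classification of MCI from normed test scores.

The classifier consumes age-, sex- and education-adjusted z-scores for ten
neuropsychological instruments, two per cognitive domain (memory, executive
function, attention, language, visuospatial), plus the count of dependent
Lawton-Brody instrumental-activity items.  A score is *impaired* when it
lies strictly more than ``cutoff_sd`` standard deviations below the
normative mean (z = -1.0 exactly is unimpaired).  A subject is MCI when any
of three rules fires:

1. both measures impaired within at least one domain;
2. at least one impaired measure in each of three of the five domains;
3. a Lawton-Brody score of 4 (dependence on all four instrumental items).

Rule 1 is evaluated over all five domains by default; ``rule1_domains``
restricts it (the narrower memory/language/executive variant is a
documented option).  Normative adjustment happens upstream; raw test
scoring is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: domain -> (instrument z-score columns), two measures per domain
DOMAINS: dict[str, tuple[str, str]] = {
    "memory": ("z_fcsrt_free", "z_benson_delay"),
    "executive": ("z_trails_b", "z_fluency_letter"),
    "attention": ("z_trails_a", "z_number_span"),
    "language": ("z_mint", "z_fluency_category"),
    "visuospatial": ("z_benson_copy", "z_block_design"),
}

INSTRUMENTS: tuple[str, ...] = tuple(m for pair in DOMAINS.values() for m in pair)


class ClassificationError(ValueError):
    """A required score is missing or out of range."""


@dataclass(frozen=True)
class NeuropsychScores:
    """Ten instrument z-scores plus the Lawton-Brody dependence count."""

    zscores: Mapping[str, float]
    lawton_brody: int

    def __post_init__(self) -> None:
        for name in INSTRUMENTS:
            z = self.zscores.get(name)
            if z is None or (isinstance(z, float) and np.isnan(z)):
                raise ClassificationError(f"missing z-score for {name}")
        lb = self.lawton_brody
        if not (isinstance(lb, (int, np.integer)) and 0 <= lb <= 4):
            raise ClassificationError("lawton_brody must be an integer in [0, 4]")

    @classmethod
    def from_row(cls, row: Mapping[str, float]) -> "NeuropsychScores":
        return cls({k: row[k] for k in INSTRUMENTS if k in row},
                   int(row["lawton_brody"]))


@dataclass
class Classification:
    status: str  # "MCI" or "CN"
    rules_fired: list[int] = field(default_factory=list)
    impaired_domains: list[str] = field(default_factory=list)  # rule-1 sense
    domains_with_any_impairment: list[str] = field(default_factory=list)


def domain_impairment_flags(
    scores: NeuropsychScores, cutoff_sd: float = 1.0
) -> dict[str, bool]:
    """Per-domain rule-1 flags: both measures strictly below ``-cutoff_sd``.

    These flags feed the domain-specific model runs (the analysis replaces
    the MCI indicator with one of them).
    """
    return {
        dom: all(scores.zscores[m] < -cutoff_sd for m in pair)
        for dom, pair in DOMAINS.items()
    }


def classify_jak_bondi(
    scores: NeuropsychScores,
    cutoff_sd: float = 1.0,
    rule1_domains: Iterable[str] | None = None,
) -> Classification:
    """Apply the three actuarial rules; returns status plus a rule trace."""
    doms = tuple(rule1_domains) if rule1_domains is not None else tuple(DOMAINS)
    unknown = set(doms) - set(DOMAINS)
    if unknown:
        raise ClassificationError(f"unknown domains {sorted(unknown)}")

    both = domain_impairment_flags(scores, cutoff_sd)
    any_imp = {
        dom: any(scores.zscores[m] < -cutoff_sd for m in pair)
        for dom, pair in DOMAINS.items()
    }
    rules: list[int] = []
    if any(both[d] for d in doms):
        rules.append(1)
    if sum(any_imp.values()) >= 3:
        rules.append(2)
    if scores.lawton_brody == 4:
        rules.append(3)
    return Classification(
        status="MCI" if rules else "CN",
        rules_fired=rules,
        impaired_domains=[d for d in doms if both[d]],
        domains_with_any_impairment=[d for d, v in any_imp.items() if v],
    )


def classify_cohort(
    scores_df: pd.DataFrame,
    cutoff_sd: float = 1.0,
    rule1_domains: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Classify every row of a scores table (needs the instrument columns,
    ``lawton_brody`` and ``subject_id``).

    Returns one row per subject with ``status``, ``mci`` (0/1),
    ``rules_fired`` and per-domain ``impaired_<domain>`` flags.
    """
    records = []
    for _, row in scores_df.iterrows():
        sc = NeuropsychScores.from_row(row)
        cls = classify_jak_bondi(sc, cutoff_sd, rule1_domains)
        rec = {
            "subject_id": row["subject_id"],
            "status": cls.status,
            "mci": int(cls.status == "MCI"),
            "rules_fired": ",".join(map(str, cls.rules_fired)),
        }
        for dom, flag in domain_impairment_flags(sc, cutoff_sd).items():
            rec[f"impaired_{dom}"] = int(flag)
        records.append(rec)
    return pd.DataFrame(records)
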