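"""Species-pool accounting: frequency tallies, Chao richness estimation,
checklist reconciliation, the regional-extinction rule, and turnover.

The Chao1 estimator extrapolates total richness from the counts of
species seen exactly once (singletons, f1) and exactly twice
(doubletons, f2):

    S_chao = S_obs + f1^2 / (2 f2)            (classic, f2 > 0)
    S_chao = S_obs + f1 (f1 - 1) / (2 (f2+1)) (bias-corrected)

Checklist reconciliation applies an auditable ledger of taxonomic
actions (merges, exclusions, additions) to a base name list; turnover
between two checklist snapshots is reported as
100 * (|losses| + |gains|) / (2 * S_ref).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from porelist.records import OccurrenceRecord


class ChaoVariant(str, enum.Enum):
    classic = "classic"
    bias_corrected = "bias_corrected"


@dataclass
class RichnessSummary:
    """Observed richness with singleton/doubleton tallies and, once
    computed, the Chao estimate."""

    S_obs: int
    f1: int
    f2: int
    S_chao: Optional[float] = None
    estimator_variant: Optional[ChaoVariant] = None

    def __post_init__(self) -> None:
        if min(self.S_obs, self.f1, self.f2) < 0:
            raise ValueError("negative tally")
        if self.f1 + self.f2 > self.S_obs:
            raise ValueError("f1 + f2 cannot exceed S_obs")


def tally_frequencies(records: Iterable[OccurrenceRecord]
                      ) -> tuple[Counter, RichnessSummary]:
    """Exact per-species record counts plus the richness summary
    (without the Chao estimate)."""
    counts: Counter = Counter(r.species_id for r in records)
    f1 = sum(1 for c in counts.values() if c == 1)
    f2 = sum(1 for c in counts.values() if c == 2)
    return counts, RichnessSummary(S_obs=len(counts), f1=f1, f2=f2)


def chao1(S_obs: int, f1: int, f2: int,
          variant: ChaoVariant | str = ChaoVariant.classic) -> float:
    """Chao1 estimate of total species richness.

    The classic form S_obs + f1^2/(2 f2) applies when doubletons exist;
    with f2 = 0 it falls back to the bias-corrected singleton term
    S_obs + f1(f1-1)/2.  The raw (unrounded) estimate is returned;
    rounding is a reporting concern.
    """
    if min(S_obs, f1, f2) < 0:
        raise ValueError("tallies must be non-negative")
    if f1 + f2 > S_obs:
        raise ValueError("f1 + f2 cannot exceed S_obs")
    variant = ChaoVariant(variant)
    if variant is ChaoVariant.bias_corrected:
        return S_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return S_obs + f1 * f1 / (2.0 * f2)
    return S_obs + f1 * (f1 - 1) / 2.0


def summarize_richness(records: Iterable[OccurrenceRecord],
                       variant: ChaoVariant | str = ChaoVariant.classic
                       ) -> RichnessSummary:
    """Tally records and attach the Chao estimate in one step."""
    _, summary = tally_frequencies(records)
    summary.S_chao = chao1(summary.S_obs, summary.f1, summary.f2, variant)
    summary.estimator_variant = ChaoVariant(variant)
    return summary


# ---------------------------------------------------------------------------
# Checklist reconciliation


class LedgerAction(str, enum.Enum):
    accept = "accept"
    merge_into = "merge_into"
    exclude_unsupported = "exclude_unsupported"
    exclude_misidentified = "exclude_misidentified"
    add_new = "add_new"
    split_from = "split_from"


_REMOVALS = (LedgerAction.merge_into, LedgerAction.exclude_unsupported,
             LedgerAction.exclude_misidentified)


@dataclass
class LedgerEntry:
    name: str
    action: LedgerAction
    target: Optional[str] = None  # merge target or split source
    note: str = ""

    def __post_init__(self) -> None:
        self.action = LedgerAction(self.action)
        if self.action in (LedgerAction.merge_into, LedgerAction.split_from):
            if not self.target:
                raise ValueError(f"{self.action.value} entry for {self.name!r} "
                                 "needs a target/source name")


@dataclass
class LedgerReport:
    accepted: list[str]
    merged: list[str] = field(default_factory=list)
    excluded_unsupported: list[str] = field(default_factory=list)
    excluded_misidentified: list[str] = field(default_factory=list)
    added: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (len(self.merged) + len(self.excluded_unsupported)
                + len(self.excluded_misidentified))


def apply_ledger(base_names: Sequence[str], ledger: Sequence[LedgerEntry],
                 strict: bool = True) -> LedgerReport:
    """Apply a reconciliation ledger to a base checklist.

    The accepted list is the base minus merged/excluded names plus new
    additions; every removal traces to exactly one entry.  In strict mode
    (default) a removal referencing an unknown name, or an add_new of an
    existing name, is an error.  With ``strict=False`` such entries are
    treated as already applied and skipped, which makes re-application of
    an applied ledger a no-op (idempotence).
    """
    if len(set(base_names)) != len(base_names):
        raise ValueError("base names must be unique")
    base = set(base_names)
    report = LedgerReport(accepted=[])
    removed: set[str] = set()
    added: set[str] = set()

    for entry in ledger:
        if entry.action is LedgerAction.add_new:
            if entry.name in base or entry.name in added:
                if strict:
                    raise ValueError(f"add_new of existing name {entry.name!r}")
                continue
            added.add(entry.name)
            report.added.append(entry.name)
            continue
        if entry.name not in base:
            if strict:
                raise ValueError(f"ledger references unknown name {entry.name!r}")
            continue
        if entry.action is LedgerAction.accept:
            continue
        if entry.action is LedgerAction.split_from:
            # a split names a new taxon carved out of an existing one
            if entry.target not in base and strict:
                raise ValueError(
                    f"split_from references unknown source {entry.target!r}")
            continue
        if entry.name in removed:
            raise ValueError(f"duplicate removal of {entry.name!r}")
        removed.add(entry.name)
        if entry.action is LedgerAction.merge_into:
            report.merged.append(entry.name)
        elif entry.action is LedgerAction.exclude_unsupported:
            report.excluded_unsupported.append(entry.name)
        else:
            report.excluded_misidentified.append(entry.name)

    accepted = (base - removed) | added
    # merge targets must survive ledger application
    for entry in ledger:
        if entry.action is LedgerAction.merge_into and entry.target not in accepted:
            raise ValueError(
                f"merge target {entry.target!r} is not an accepted name")
    report.accepted = sorted(accepted)
    return report


def flag_regionally_extinct(per_species_last_year: Mapping[str, int],
                            current_year: int, horizon: int = 50) -> list[str]:
    """Names with no record for strictly more than *horizon* years.

    A gap of exactly *horizon* years does not flag.
    """
    flagged = []
    for name, last_year in per_species_last_year.items():
        if last_year > current_year:
            raise ValueError(f"{name}: last record year {last_year} is in the future")
        if current_year - last_year > horizon:
            flagged.append(name)
    return sorted(flagged)


def records_since(records: Iterable[OccurrenceRecord],
                  cutoff_year: int) -> list[str]:
    """Species whose most recent record is not after *cutoff_year*."""
    last: dict[str, int] = {}
    for rec in records:
        if rec.species_id not in last or rec.year > last[rec.species_id]:
            last[rec.species_id] = rec.year
    return sorted(name for name, year in last.items() if year <= cutoff_year)


@dataclass
class TurnoverReport:
    losses: list[str]
    gains: list[str]
    S_ref: int

    @property
    def turnover_pct(self) -> float:
        if self.S_ref == 0:
            return 0.0
        return 100.0 * (len(self.losses) + len(self.gains)) / (2.0 * self.S_ref)


def turnover(old_accepted: Sequence[str],
             new_accepted: Sequence[str]) -> TurnoverReport:
    """Species turnover between two checklist snapshots.

    Turnover percentage averages the loss rate and gain rate relative to
    the reference (old) pool: 100 (|losses|+|gains|) / (2 S_ref).
    """
    for lst, label in ((old_accepted, "old"), (new_accepted, "new")):
        if len(set(lst)) != len(lst):
            raise ValueError(f"{label} checklist contains duplicate names")
    old, new = set(old_accepted), set(new_accepted)
    return TurnoverReport(losses=sorted(old - new), gains=sorted(new - old),
                          S_ref=len(old))


def read_ledger_csv(stream) -> list[LedgerEntry]:
    """Parse a ledger CSV with columns name, action, target, note."""
    import csv

    entries = []
    for row in csv.DictReader(stream):
        entries.append(LedgerEntry(
            name=row["name"].strip(),
            action=LedgerAction(row["action"].strip()),
            target=(row.get("target") or "").strip() or None,
            note=(row.get("note") or "").strip(),
        ))
    return entries
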