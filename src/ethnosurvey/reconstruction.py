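"""Rebuild the species-by-ailment report matrix from printed survey margins.

Published consensus-index tables print margins (per-species FC and UR,
per-cell fidelity levels, per-category Nur/Ntaxa) but not the underlying
informant-level data.  Because ``FL = 100 * Np / FC`` and printed FL values
are themselves rounded from integer ratios, half-up inversion
``Np = round(FL * FC / 100)`` recovers the integer cell counts.  This
module performs that inversion, cross-checks every table against every
other (reporting, never repairing, the inconsistencies a printed study may
carry), and constructs a synthetic informant-level dataset that realizes
the margins exactly, so the whole index pipeline can be exercised on the
reference survey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .indices import choice_value, informant_consensus_factor, round_half_up
from .survey_data import (
    AmbiguousSpeciesError,
    SurveyDataset,
    UseRecord,
    ValidationError,
    load_reference_table,
    load_species_registry,
    normalize_category,
    resolve_species_name,
)

log = logging.getLogger("ethnosurvey")


class InfeasibleMarginsError(ValidationError):
    """Margins that no informant-level dataset can realize."""


@dataclass
class MarginSet:
    """Printed margins of a survey: species totals, cell FLs, category totals.

    ``cv`` and ``icf`` carry the printed index values (possibly rounded or
    slightly inconsistent) used only for cross-validation; ``cv`` keys keep
    the printed species string because entries like "Ziziphus sp." are
    deliberately ambiguous.
    """

    n_informants: int
    fc: dict[str, int]
    ur: dict[str, int]
    fl: dict[tuple[str, str], float]  # (species_id, category_id) -> percent
    nur: dict[str, int]
    ntaxa: dict[str, int]
    icf: dict[str, float] = field(default_factory=dict)
    cv: dict[tuple[str, str], float] = field(default_factory=dict)  # (cat, printed name)

    def __post_init__(self) -> None:
        missing = {s for s, _ in self.fl} - set(self.fc)
        if missing:
            raise ValidationError(
                f"species in the FL table but not the FC table: {sorted(missing)}"
            )


@dataclass(frozen=True)
class Violation:
    scope: str
    expected: object
    observed: object
    severity: str  # "info" | "warn" | "fail"
    message: str = ""

    def __str__(self) -> str:
        return (
            f"[{self.severity.upper()}] {self.scope}: expected "
            f"{self.expected}, observed {self.observed}"
            + (f" ({self.message})" if self.message else "")
        )


@dataclass
class ConsistencyReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "warn"]

    @property
    def failures(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "fail"]

    @property
    def infos(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "info"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scope": v.scope,
                    "expected": v.expected,
                    "observed": v.observed,
                    "severity": v.severity,
                    "message": v.message,
                }
                for v in self.violations
            ],
            columns=["scope", "expected", "observed", "severity", "message"],
        )

    def __str__(self) -> str:
        if self.ok:
            return "all consistency checks passed"
        lines = [str(v) for v in self.violations]
        lines.append(
            f"{len(self.failures)} failure(s), {len(self.warnings)} warning(s), "
            f"{len(self.infos)} informational note(s)"
        )
        return "\n".join(lines)


def load_reference_margins() -> MarginSet:
    """Assemble the MarginSet of the packaged reference survey (N = 200)."""
    registry = load_species_registry()
    t3 = load_reference_table("species_indices")
    t4 = load_reference_table("ailment_consensus")
    t5 = load_reference_table("choice_values")
    t6 = load_reference_table("fidelity_levels")
    fc, ur = {}, {}
    for row in t3.itertuples(index=False):
        sid = resolve_species_name(row.species, registry)
        fc[sid] = int(row.FC)
        ur[sid] = int(row.UR)
    fl = {}
    for row in t6.itertuples(index=False):
        sid = resolve_species_name(row.species, registry)
        fl[(sid, normalize_category(row.category))] = float(row.FL)
    nur, ntaxa, icf = {}, {}, {}
    for row in t4.itertuples(index=False):
        cid = normalize_category(row.category)
        nur[cid] = int(row.Nur)
        ntaxa[cid] = int(row.Ntaxa)
        icf[cid] = float(row.ICF)
    cv = {}
    for row in t5.itertuples(index=False):
        cv[(normalize_category(row.category), str(row.species))] = float(row.CV)
    return MarginSet(
        n_informants=200, fc=fc, ur=ur, fl=fl, nur=nur, ntaxa=ntaxa, icf=icf, cv=cv
    )


def reconstruct_np(margins: MarginSet) -> pd.DataFrame:
    """Invert the fidelity levels to integer cell counts.

    Returns a DataFrame with ``species_id``, ``category_id``, ``Np`` for
    every cell listed in the FL table; cells absent from it are implicitly
    zero.  A listed cell whose reconstruction is 0 is an error: a printed
    FL implies at least one citing informant.
    """
    rows = []
    for (sid, cid), fl in sorted(margins.fl.items()):
        np_ = int(round_half_up(fl * margins.fc[sid] / 100.0))
        if np_ == 0:
            raise ValidationError(
                f"cell ({sid}, {cid}) with FL={fl} reconstructs to Np=0"
            )
        rows.append({"species_id": sid, "category_id": cid, "Np": np_})
    return pd.DataFrame(rows, columns=["species_id", "category_id", "Np"])


def validate(margins: MarginSet, np_matrix: pd.DataFrame) -> ConsistencyReport:
    """Cross-check the reconstructed cell matrix against every printed margin.

    Checks, in order: (a) per-species cell sums vs UR, (b) per-category
    cell sums vs Nur, (c) distinct cited taxa vs Ntaxa, (d) recomputed
    choice values vs the printed ones, (e) recomputed consensus factors vs
    the printed ones, plus the grand totals of UR and Nur.  Mismatches
    against printed tables are warnings (a published table can be
    internally inconsistent; the validator reports, never repairs), and
    arithmetic consequences of an already-flagged margin are informational.
    """
    report = ConsistencyReport()
    cells = np_matrix
    sp_sum = cells.groupby("species_id")["Np"].sum().to_dict()
    cat_sum = cells.groupby("category_id")["Np"].sum().to_dict()
    cat_taxa = cells.groupby("category_id")["species_id"].nunique().to_dict()

    # (a) species totals
    for sid, ur in sorted(margins.ur.items()):
        observed = int(sp_sum.get(sid, 0))
        if observed != ur:
            report.violations.append(
                Violation(f"({sid}, UR)", ur, observed, "warn",
                          "cell sums disagree with the species use-report total")
            )

    # (b) + (c) category totals; consequences downgrade to info
    flagged_nur, flagged_ntaxa = set(), set()
    for cid, nur in sorted(margins.nur.items()):
        observed = int(cat_sum.get(cid, 0))
        if observed != nur:
            flagged_nur.add(cid)
            report.violations.append(
                Violation(f"({cid}, Nur)", nur, observed, "warn",
                          "cell sums disagree with the category report total")
            )
    for cid, ntaxa in sorted(margins.ntaxa.items()):
        observed = int(cat_taxa.get(cid, 0))
        if observed != ntaxa:
            flagged_ntaxa.add(cid)
            report.violations.append(
                Violation(f"({cid}, Ntaxa)", ntaxa, observed, "warn",
                          "distinct cited taxa disagree with the printed count")
            )

    # (d) choice values, recomputed from the data-derived Ntaxa
    registry = load_species_registry() if margins.cv else {}
    np_lookup = {
        (r.species_id, r.category_id): int(r.Np)
        for r in cells.itertuples(index=False)
    }
    for (cid, printed_name), cv_printed in sorted(margins.cv.items()):
        try:
            candidates = [resolve_species_name(printed_name, registry)]
        except AmbiguousSpeciesError as exc:
            candidates = list(exc.candidates)
        ntaxa_c = int(cat_taxa.get(cid, 0))
        if ntaxa_c == 0:
            continue
        recomputed = [
            round_half_up(choice_value(np_lookup.get((sid, cid), 0), ntaxa_c), 2)
            for sid in candidates
        ]
        if not any(abs(r - cv_printed) < 1e-9 for r in recomputed):
            report.violations.append(
                Violation(
                    f"({cid}, {printed_name}, CV)", cv_printed,
                    recomputed[0] if len(recomputed) == 1 else recomputed,
                    "info", "recomputed choice value differs from the printed one",
                )
            )

    # (e) consensus factors, recomputed from the data-derived margins
    for cid, icf_printed in sorted(margins.icf.items()):
        nur_d = int(cat_sum.get(cid, 0))
        ntaxa_d = int(cat_taxa.get(cid, 0))
        if ntaxa_d == 0:
            continue
        recomputed = round_half_up(informant_consensus_factor(nur_d, ntaxa_d), 2)
        if abs(recomputed - icf_printed) > 1e-9:
            report.violations.append(
                Violation(
                    f"({cid}, ICF)", icf_printed, recomputed, "info",
                    "consequence of an already-flagged margin mismatch",
                )
            )

    # grand totals
    total_ur = sum(margins.ur.values())
    total_nur = sum(margins.nur.values())
    if total_ur != total_nur:
        report.violations.append(
            Violation("(grand total, UR vs Nur)", total_ur, total_nur, "info",
                      "species and category tables disagree on the total "
                      "number of use reports")
        )
    return report


def realize_dataset(
    np_matrix: pd.DataFrame,
    fc: dict[str, int],
    n_informants: int,
    seed: Optional[int] = None,
) -> SurveyDataset:
    """Construct an informant-level dataset whose tallies equal the margins.

    For each species with frequency of citation ``FC`` the realization
    creates ``FC`` informant slots and deals each category's ``Np``
    citations onto consecutive slots (wrapping), continuing the pointer
    across categories; with ``max Np <= FC <= sum Np`` this guarantees each
    category hits distinct slots and every slot receives at least one
    citation, so ``tally`` returns exactly the input Np, FC and
    ``UR = sum Np``.  Informant ids are namespaced per species (printed
    tables carry no informant co-citation information, so overlap across
    species is not modeled).  ``seed`` only permutes the synthetic
    informant labels; the realized margins are seed-independent.
    """
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[tuple[str, int]]] = {}
    for row in np_matrix.itertuples(index=False):
        by_species.setdefault(row.species_id, []).append(
            (row.category_id, int(row.Np))
        )
    records = []
    for sid in sorted(by_species):
        fc_s = int(fc[sid])
        cats = sorted(by_species[sid])
        total = sum(np_ for _, np_ in cats)
        max_np = max(np_ for _, np_ in cats)
        if max_np > fc_s:
            raise InfeasibleMarginsError(
                f"{sid}: a cell count Np={max_np} exceeds FC={fc_s}"
            )
        if fc_s > total:
            raise InfeasibleMarginsError(
                f"{sid}: FC={fc_s} exceeds the total of cell counts {total}"
            )
        labels = [f"{sid}#i{k:03d}" for k in range(fc_s)]
        if seed is not None:
            rng.shuffle(labels)
        ptr = 0
        for cid, np_ in cats:
            for k in range(np_):
                records.append(
                    UseRecord(
                        informant_id=labels[(ptr + k) % fc_s],
                        species_id=sid,
                        category_id=cid,
                    )
                )
            ptr = (ptr + np_) % fc_s
    return SurveyDataset(records=tuple(records), n_informants=n_informants)


def realize_reference_dataset(seed: Optional[int] = None) -> SurveyDataset:
    """Margins -> cell matrix -> informant-level dataset, for the packaged survey."""
    margins = load_reference_margins()
    cells = reconstruct_np(margins)
    return realize_dataset(cells, margins.fc, margins.n_informants, seed=seed)


def validate_reference() -> ConsistencyReport:
    """Reconstruct the packaged survey and run the full consistency suite."""
    margins = load_reference_margins()
    cells = reconstruct_np(margins)
    return validate(margins, cells)
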