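"""Consensus indices for informant use-report surveys.

All ten indices reduce to three tallies over the deduplicated
(informant, species, category) triples:

* per species *s*: use reports ``UR_s`` (triples), frequency of citation
  ``FC_s`` (distinct informants), number of uses ``NU_s`` (distinct
  categories);
* per ailment category *c*: ``Nur_c`` (triples) and ``Ntaxa_c`` (distinct
  species);
* per cell (*s*, *c*): ``Np_sc`` (distinct informants citing *s* for *c*).

From those:

* use value            ``UV_s  = UR_s / N``
* relative frequency   ``RFC_s = FC_s / N``
* cultural importance  ``CI_s  = UR_s / N`` (one report per
  informant-species-category, so CI coincides with UV)
* relative importance  ``RI_s  = (RFC_s / max RFC + NU_s / max NU) / 2``
* informant consensus  ``ICF_c = (Nur_c - Ntaxa_c) / (Nur_c - 1)``,
  with ``ICF = 0`` when ``Nur <= 1`` (the 0/0 case)
* fidelity level       ``FL_sc = 100 * Np_sc / FC_s``
* choice value         ``CV_sc = Np_sc / Ntaxa_c``

Table emission rounds half-up: UV/RFC/CI/RI to 3 decimals, ICF/FL/CV to 2.
Internal values stay unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Union

import pandas as pd

from .survey_data import SurveyDataset, ValidationError

Number = Union[int, float]


def round_half_up(value: Number, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Uses the shortest decimal representation of the float, so values such
    as 0.855 and 46.9974 round the way they read, not the way IEEE-754
    stores them.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TallyResult:
    """Raw counts underlying every index."""

    species: pd.DataFrame  # species_id, UR, FC, NU
    categories: pd.DataFrame  # category_id, Nur, Ntaxa
    cells: pd.DataFrame  # species_id, category_id, Np


@dataclass
class SummaryTables:
    """The four index tables a survey report prints."""

    species: pd.DataFrame  # UR, UV, FC, RFC, CI, RI, NU
    categories: pd.DataFrame  # Nur, Ntaxa, ICF
    fidelity: pd.DataFrame  # species, category, Np, FL
    choice: pd.DataFrame  # category, species, Np, CV


def tally(dataset: SurveyDataset) -> TallyResult:
    """Count UR/FC/NU per species, Nur/Ntaxa per category, Np per cell.

    Conservation holds by construction: the per-category Np of a species
    sum to its UR, and the per-species Np of a category sum to its Nur.
    """
    df = dataset.to_frame()
    if df.empty:
        empty_sp = pd.DataFrame(columns=["species_id", "UR", "FC", "NU"])
        empty_cat = pd.DataFrame(columns=["category_id", "Nur", "Ntaxa"])
        empty_cell = pd.DataFrame(columns=["species_id", "category_id", "Np"])
        return TallyResult(empty_sp, empty_cat, empty_cell)
    cells = (
        df.groupby(["species_id", "category_id"])["informant_id"]
        .nunique()
        .rename("Np")
        .reset_index()
        .sort_values(["species_id", "category_id"], ignore_index=True)
    )
    species = (
        df.groupby("species_id")
        .agg(
            UR=("informant_id", "size"),
            FC=("informant_id", "nunique"),
            NU=("category_id", "nunique"),
        )
        .reset_index()
        .sort_values("species_id", ignore_index=True)
    )
    categories = (
        df.groupby("category_id")
        .agg(Nur=("informant_id", "size"), Ntaxa=("species_id", "nunique"))
        .reset_index()
        .sort_values("category_id", ignore_index=True)
    )
    return TallyResult(species, categories, cells)


# ---------------------------------------------------------------------------
# Scalar index formulas
# ---------------------------------------------------------------------------


def use_value(ur: int, n: int) -> float:
    """UV = UR / N."""
    if n <= 0:
        raise ValidationError("N must be positive")
    return ur / n


def relative_frequency_of_citation(fc: int, n: int) -> float:
    """RFC = FC / N, in [0, 1]."""
    if n <= 0:
        raise ValidationError("N must be positive")
    if fc > n:
        raise ValidationError(f"FC={fc} cannot exceed N={n}")
    return fc / n


def cultural_importance(ur: int, n: int) -> float:
    """CI = UR / N under the one-report-per-triple convention (equals UV)."""
    return use_value(ur, n)


def informant_consensus_factor(nur: int, ntaxa: int) -> float:
    """ICF = (Nur - Ntaxa) / (Nur - 1); 0 when Nur <= 1 (degenerate 0/0)."""
    if ntaxa < 1:
        raise ValidationError("Ntaxa must be at least 1")
    if ntaxa > nur:
        raise ValidationError(f"Ntaxa={ntaxa} cannot exceed Nur={nur}")
    if nur <= 1:
        return 0.0
    return (nur - ntaxa) / (nur - 1)


def fidelity_level(np_count: int, fc: int) -> float:
    """FL = 100 * Np / FC, the share of a species' informants behind one use."""
    if fc <= 0:
        raise ValidationError("FC must be positive")
    if np_count > fc:
        raise ValidationError(f"Np={np_count} cannot exceed FC={fc}")
    return 100.0 * np_count / fc


def choice_value(np_count: int, ntaxa_c: int) -> float:
    """CV = Np / Ntaxa of the category; ranks preferred species per ailment."""
    if ntaxa_c <= 0:
        raise ValidationError("Ntaxa must be positive")
    return np_count / ntaxa_c


def relative_importance(
    rfc: float, nu: int, max_rfc: float, max_nu: int
) -> float:
    """RI = (RFC/max RFC + NU/max NU) / 2; 1 for the species maximal in both."""
    if max_rfc <= 0 or max_nu <= 0:
        raise ValidationError("maxima must be positive (empty species table?)")
    return (rfc / max_rfc + nu / max_nu) / 2.0


# ---------------------------------------------------------------------------
# One-pass summary
# ---------------------------------------------------------------------------


def summarize(dataset: SurveyDataset, rounded: bool = True) -> SummaryTables:
    """Produce all four index tables from a dataset in one pass.

    Rows are ordered alphabetically by species id and category id.  With
    ``rounded`` (the default) UV/RFC/CI/RI carry 3 decimals and ICF/FL/CV
    2, half-up; pass ``rounded=False`` for the unrounded values used in
    invariance tests.
    """
    t = tally(dataset)
    n = dataset.n_informants

    sp = t.species.copy()
    if sp.empty:
        species = pd.DataFrame(
            columns=["species_id", "UR", "UV", "FC", "RFC", "CI", "RI", "NU"]
        )
    else:
        sp["UV"] = sp["UR"] / n
        sp["RFC"] = sp["FC"] / n
        sp["CI"] = sp["UR"] / n
        max_rfc, max_nu = sp["RFC"].max(), sp["NU"].max()
        sp["RI"] = (sp["RFC"] / max_rfc + sp["NU"] / max_nu) / 2.0
        species = sp[["species_id", "UR", "UV", "FC", "RFC", "CI", "RI", "NU"]].copy()

    cat = t.categories.copy()
    if cat.empty:
        categories = pd.DataFrame(columns=["category_id", "Nur", "Ntaxa", "ICF"])
    else:
        cat["ICF"] = [
            informant_consensus_factor(nur, ntaxa)
            for nur, ntaxa in zip(cat["Nur"], cat["Ntaxa"])
        ]
        categories = cat[["category_id", "Nur", "Ntaxa", "ICF"]].copy()

    cells = t.cells.copy()
    if cells.empty:
        fidelity = pd.DataFrame(columns=["species_id", "category_id", "Np", "FL"])
        choice = pd.DataFrame(columns=["category_id", "species_id", "Np", "CV"])
    else:
        fc_map = t.species.set_index("species_id")["FC"]
        ntaxa_map = t.categories.set_index("category_id")["Ntaxa"]
        cells["FL"] = [
            fidelity_level(np_, int(fc_map[sid]))
            for sid, np_ in zip(cells["species_id"], cells["Np"])
        ]
        cells["CV"] = [
            choice_value(np_, int(ntaxa_map[cid]))
            for cid, np_ in zip(cells["category_id"], cells["Np"])
        ]
        fidelity = cells[["species_id", "category_id", "Np", "FL"]].copy()
        choice = (
            cells[["category_id", "species_id", "Np", "CV"]]
            .sort_values(
                ["category_id", "CV", "species_id"],
                ascending=[True, False, True],
                ignore_index=True,
            )
            .copy()
        )

    if rounded:
        for col in ("UV", "RFC", "CI", "RI"):
            if len(species):
                species[col] = species[col].map(lambda v: round_half_up(v, 3))
        if len(categories):
            categories["ICF"] = categories["ICF"].map(
                lambda v: round_half_up(v, 2)
            )
        if len(fidelity):
            fidelity["FL"] = fidelity["FL"].map(lambda v: round_half_up(v, 2))
        if len(choice):
            choice["CV"] = choice["CV"].map(lambda v: round_half_up(v, 2))

    return SummaryTables(
        species=species.reset_index(drop=True),
        categories=categories.reset_index(drop=True),
        fidelity=fidelity.reset_index(drop=True),
        choice=choice,
    )
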