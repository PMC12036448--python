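"""Glucuronidation pattern queries: neutral-loss + product-ion filtering.

A :class:`PatternQuery` is the declarative fingerprint of glucuronidation in
MS/MS data: a set of neutral-loss clauses combined by OR (loss of the
dehydrated moiety at 176.0321 Da, or of intact glucuronic acid at
194.0425 Da) and a set of product-ion clauses combined by AND (the
glucuronate fragments at 113.0244 and 85.0295 in negative mode).  Each
clause carries an m/z tolerance (default 0.003 Da, inclusive) and a
relative-intensity floor expressed as percent of the base peak (inclusive).

Neutral losses are computed as ``precursor_mz - fragment_mz`` assuming a
singly charged precursor; multiply charged spectra are skipped with a
warning by the collection-level filter.

Galacturonic-acid conjugates (the C6 epimer) satisfy the same fingerprint
but show a distinguishing high-intensity fragment near m/z 115.0038; the
classifier reports such spectra as ``galacturonide_suspect`` rather than
silently dropping them, mirroring a visual-inspection QC step.  The decoy
based :func:`estimate_fdr` can count suspects as negatives (``veto=True``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import chem
from .spectra import Spectrum, SpectrumCollection

logger = logging.getLogger(__name__)

__all__ = [
    "NeutralLossClause",
    "ProductIonClause",
    "PatternQuery",
    "IsomerRule",
    "GlucuronideCall",
    "FdrReport",
    "neutral_loss_matches",
    "product_ion_matches",
    "evaluate_query",
    "classify_spectrum",
    "filter_collection",
    "estimate_fdr",
    "default_queries",
]

DEFAULT_TOL_DA = 0.003


@dataclass(frozen=True)
class NeutralLossClause:
    """Match fragments at ``precursor - target_nl`` within ``tol``."""

    target_nl: float
    tol: float = DEFAULT_TOL_DA
    min_intensity_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0 <= self.min_intensity_pct <= 100:
            raise ValueError("min_intensity_pct must be in [0, 100]")


@dataclass(frozen=True)
class ProductIonClause:
    """Match fragments at ``target_mz`` within ``tol``."""

    target_mz: float
    tol: float = DEFAULT_TOL_DA
    min_intensity_pct: float = 0.0

    __post_init__ = NeutralLossClause.__post_init__


@dataclass(frozen=True)
class IsomerRule:
    """Galacturonide discriminator: fragment near 115.0038 at high intensity."""

    target_mz: float = chem.FRAG_GALACTURONIDE_115
    tol: float = DEFAULT_TOL_DA
    min_intensity_pct: float = 10.0


@dataclass(frozen=True)
class PatternQuery:
    """Neutral-loss clauses OR-combined AND product-ion clauses AND-combined."""

    name: str
    polarity: str
    nl_clauses: tuple[NeutralLossClause, ...] = ()
    prod_clauses: tuple[ProductIonClause, ...] = ()

    def __post_init__(self) -> None:
        if not self.nl_clauses and not self.prod_clauses:
            raise ValueError("a query needs at least one clause")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        object.__setattr__(self, "nl_clauses", tuple(self.nl_clauses))
        object.__setattr__(self, "prod_clauses", tuple(self.prod_clauses))

    def without_products(self) -> "PatternQuery":
        """The neutral-loss-only relaxation of this query."""
        return replace(self, name=f"{self.name}_nl_only", prod_clauses=())


@dataclass
class GlucuronideCall:
    """Decision for one spectrum, with the matched evidence."""

    scan_id: str
    is_match: bool
    galacturonide_suspect: bool = False
    matched_nl: list[tuple[float, float]] = field(default_factory=list)  # (target_nl, frag mz)
    matched_products: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class FdrReport:
    """Confusion counts of a query against labeled spectra.

    ``fdr`` = fp / (fp + tp) (0 when no positives); ``sensitivity`` =
    tp / (tp + fn).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def fdr(self) -> float:
        return self.fp / (self.fp + self.tp) if (self.fp + self.tp) else 0.0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _matches(
    spectrum: Spectrum, target_mz: float, tol: float, min_pct: float
) -> list[tuple[float, float]]:
    """(fragment mz, relative intensity) of peaks within tol and above floor."""
    pct = spectrum.relative_intensity()
    keep = (np.abs(spectrum.mz - target_mz) <= tol) & (pct >= min_pct)
    return list(zip(spectrum.mz[keep].tolist(), pct[keep].tolist()))


def neutral_loss_matches(spectrum: Spectrum, clause: NeutralLossClause) -> list[tuple[float, float]]:
    """Fragments whose loss from the precursor matches the clause.

    Returns ``(fragment_mz, intensity_pct)`` pairs with
    ``|precursor - mz - target_nl| <= tol`` and intensity above the floor.
    """
    if not spectrum.precursor_mz > 0:
        raise ValueError("spectrum has no precursor m/z")
    return _matches(
        spectrum, spectrum.precursor_mz - clause.target_nl, clause.tol, clause.min_intensity_pct
    )


def product_ion_matches(spectrum: Spectrum, clause: ProductIonClause) -> list[tuple[float, float]]:
    """Fragments at the clause's target m/z within tolerance and above floor."""
    return _matches(spectrum, clause.target_mz, clause.tol, clause.min_intensity_pct)


def evaluate_query(spectrum: Spectrum, query: PatternQuery) -> GlucuronideCall:
    """Evaluate the fingerprint: (OR over NL clauses) AND (AND over products).

    A polarity mismatch raises (it is not a silent non-match).  With no NL
    clauses the OR is vacuously true; the same holds for an empty product set.
    """
    if spectrum.polarity != query.polarity:
        raise ValueError(
            f"spectrum {spectrum.scan_id!r} is {spectrum.polarity}, query "
            f"{query.name!r} expects {query.polarity}"
        )
    matched_nl: list[tuple[float, float]] = []
    for cl in query.nl_clauses:
        matched_nl += [(cl.target_nl, mz) for mz, _ in neutral_loss_matches(spectrum, cl)]
    nl_ok = bool(matched_nl) or not query.nl_clauses

    matched_products: list[tuple[float, float]] = []
    prod_ok = True
    for cl in query.prod_clauses:
        hits = product_ion_matches(spectrum, cl)
        if hits:
            matched_products += [(cl.target_mz, mz) for mz, _ in hits]
        else:
            prod_ok = False
    is_match = nl_ok and prod_ok
    return GlucuronideCall(
        scan_id=spectrum.scan_id,
        is_match=is_match,
        matched_nl=matched_nl if is_match or matched_nl else [],
        matched_products=matched_products,
    )


def classify_spectrum(
    spectrum: Spectrum, query: PatternQuery, isomer_rule: IsomerRule | None = None
) -> GlucuronideCall:
    """Evaluate the query and flag galacturonide suspects among the matches."""
    rule = isomer_rule or IsomerRule()
    call = evaluate_query(spectrum, query)
    if call.is_match:
        call.galacturonide_suspect = bool(
            _matches(spectrum, rule.target_mz, rule.tol, rule.min_intensity_pct)
        )
    return call


def filter_collection(
    collection: SpectrumCollection,
    query: PatternQuery,
    isomer_rule: IsomerRule | None = None,
) -> pd.DataFrame:
    """Classify every spectrum of the query's polarity; order preserved.

    Returns a table with columns ``scan_id, precursor_mz, is_match,
    galacturonide_suspect, matched_nl, matched_products`` (evidence columns
    as ``target:fragment`` strings).  Multiply charged spectra are skipped
    with a warning, as the neutral-loss arithmetic assumes charge 1.
    """
    rows = []
    n_skipped = 0
    for s in collection:
        if s.charge != 1:
            logger.warning("scan %r has charge %d; skipped (charge-1 arithmetic)", s.scan_id, s.charge)
            n_skipped += 1
            continue
        call = classify_spectrum(s, query, isomer_rule)
        rows.append(
            {
                "scan_id": s.scan_id,
                "precursor_mz": s.precursor_mz,
                "is_match": call.is_match,
                "galacturonide_suspect": call.galacturonide_suspect,
                "matched_nl": ";".join(f"{t:.4f}:{m:.4f}" for t, m in call.matched_nl),
                "matched_products": ";".join(f"{t:.4f}:{m:.4f}" for t, m in call.matched_products),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "scan_id",
            "precursor_mz",
            "is_match",
            "galacturonide_suspect",
            "matched_nl",
            "matched_products",
        ],
    )
    logger.info(
        "pattern filter %r: %d/%d matched (%d galacturonide suspects, %d skipped)",
        query.name,
        int(out["is_match"].sum()) if len(out) else 0,
        len(out),
        int(out["galacturonide_suspect"].sum()) if len(out) else 0,
        n_skipped,
    )
    return out


def estimate_fdr(
    collection: SpectrumCollection,
    labels: Mapping[str, str] | pd.DataFrame,
    query: PatternQuery,
    isomer_rule: IsomerRule | None = None,
    veto: bool = False,
    positive_classes: Iterable[str] = ("glucuronide",),
) -> FdrReport:
    """Confusion counts of the pattern filter against ground-truth labels.

    ``labels`` maps every scan_id to its true class (or is a DataFrame with
    ``scan_id`` and ``true_class`` columns); spectra whose class is in
    ``positive_classes`` are the positives.  With ``veto=True`` galacturonide
    suspects are counted as negative calls.
    """
    if isinstance(labels, pd.DataFrame):
        labels = dict(zip(labels["scan_id"].astype(str), labels["true_class"].astype(str)))
    missing = [s.scan_id for s in collection if s.scan_id not in labels]
    if missing:
        raise ValueError(f"unlabeled scan(s): {missing[:5]}")
    positive_classes = set(positive_classes)
    table = filter_collection(collection, query, isomer_rule)
    tp = fp = fn = tn = 0
    for _, row in table.iterrows():
        predicted = bool(row["is_match"]) and not (veto and bool(row["galacturonide_suspect"]))
        truth = labels[row["scan_id"]] in positive_classes
        if predicted and truth:
            tp += 1
        elif predicted:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    return FdrReport(tp=tp, fp=fp, fn=fn, tn=tn)


def default_queries() -> dict[str, PatternQuery]:
    """The four shipped fingerprint queries.

    ``neg_standards``/``neg_biological``: both glucuronide neutral losses
    OR-combined plus the 113.0244 and 85.0295 product ions; the biological
    variant adds relative-intensity floors (5% on the loss fragment, 3% on
    the products) to tolerate MS/MS noise in biological samples.
    ``pos_standards``/``pos_biological``: neutral losses only, since the
    glucuronate product ions are a negative-mode signature.
    All tolerances are 0.003 Da.
    """
    nls = (chem.GLUCURONIDE_NL, chem.GLUCURONIC_ACID_NL)
    prods = (chem.FRAG_GLUCURONATE_113, chem.FRAG_GLUCURONATE_85)
    return {
        "neg_standards": PatternQuery(
            name="neg_standards",
            polarity="negative",
            nl_clauses=tuple(NeutralLossClause(t) for t in nls),
            prod_clauses=tuple(ProductIonClause(t) for t in prods),
        ),
        "neg_biological": PatternQuery(
            name="neg_biological",
            polarity="negative",
            nl_clauses=tuple(NeutralLossClause(t, min_intensity_pct=5.0) for t in nls),
            prod_clauses=tuple(ProductIonClause(t, min_intensity_pct=3.0) for t in prods),
        ),
        "pos_standards": PatternQuery(
            name="pos_standards",
            polarity="positive",
            nl_clauses=tuple(NeutralLossClause(t) for t in nls),
        ),
        "pos_biological": PatternQuery(
            name="pos_biological",
            polarity="positive",
            nl_clauses=tuple(NeutralLossClause(t, min_intensity_pct=5.0) for t in nls),
        ),
    }
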