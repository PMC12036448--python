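"""Labeled synthetic conjugate spectra and multi-matrix feature tables.

The generator emulates the data the fingerprinting method assumes:

* aglycone MS/MS spectra with random fragments below the precursor;
* conjugates built by shifting the precursor by an exact moiety mass
  (glucuronide/galacturonide +176.0321 Da, sulfate +79.9568 Da) while
  retaining the aglycone fragments -- the retained fragment at the
  aglycone's precursor m/z produces the diagnostic neutral loss;
* glucuronides add the 113.0244/85.0295 glucuronate product ions;
  galacturonide decoys share the neutral loss and (with probability
  ``decoy_product_prob``, emulating variable fragmentation efficiency) the
  product ions, but always carry the discriminating 115.0038 fragment;
  sulfates add no diagnostic products;
* optional uniform noise peaks whose intensity stays below the lowest
  query floor, so default noise cannot flip a classification;
* "family" variants whose aglycones share a core fragment set, emulating
  metabolite classes (e.g. flavonoids) that form dense network components;
* three-matrix feature tables (colon, serum, urine) with planted
  microbiome-driven shifts: colon depletion with paired serum/urine
  enrichment of the same conjugate features.

All randomness flows from a single ``numpy.random.Generator`` seeded from
``SynthConfig.seed``; a fixed seed reproduces outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chem
from .io import FeatureTable
from .spectra import Spectrum, SpectrumCollection

__all__ = [
    "SynthConfig",
    "MOIETY_MASSES",
    "CLASSES",
    "make_aglycone_spectrum",
    "conjugate",
    "make_labeled_dataset",
    "make_conjugate_network_dataset",
    "make_planted_table",
    "make_feature_tables",
]

#: Exact monoisotopic moiety masses added to the aglycone precursor.
MOIETY_MASSES: dict[str, float] = {
    "glucuronide": chem.GLUCURONIDE_NL,
    "galacturonide": chem.GLUCURONIDE_NL,  # isomeric with glucuronide
    "sulfate": chem.SULFATE_MOIETY,
}

CLASSES = ("aglycone", "glucuronide", "galacturonide_decoy", "sulfate", "noise")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic spectra.

    Intensity ranges are percent of the base peak.  Diagnostic intensities
    (product ions and the 115.0038 decoy discriminator) default to 20-80%,
    comfortably above the biological query floors (3-5%) and the 10%
    galacturonide veto; noise intensities stay below 3% so noise peaks can
    never satisfy a floored clause.
    """

    seed: int = 0
    n_per_class: int = 50
    aglycone_mz_range: tuple[float, float] = (150.0, 450.0)
    n_fragments: tuple[int, int] = (4, 10)
    diagnostic_intensity_pct: tuple[float, float] = (20.0, 80.0)
    nl_fragment_intensity_pct: tuple[float, float] = (20.0, 100.0)
    noise_peaks: tuple[int, int] = (0, 5)
    noise_intensity_pct: tuple[float, float] = (0.5, 2.9)
    decoy_product_prob: float = 0.7
    fragment_jitter: tuple[float, float] = (0.5, 1.5)
    fragment_dropout: float = 0.2
    polarity: str = "negative"
    rt_range: tuple[float, float] = (60.0, 1200.0)
    # family structure for network datasets
    n_families: int = 4
    family_size: int = 15
    n_core_fragments: int = 6
    n_unique_fragments: int = 3

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _uniform(rng: np.random.Generator, rng_pair) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi))


def make_aglycone_spectrum(
    rng: np.random.Generator,
    config: SynthConfig,
    scan_id: str = "aglycone_0000",
    core_mz: np.ndarray | None = None,
    core_intensity: np.ndarray | None = None,
) -> Spectrum:
    """Random aglycone spectrum: fragments below the precursor, base peak 100.

    With ``core_mz``/``core_intensity`` given, those fragments are included
    (intensities jittered) alongside ``n_unique_fragments`` random ones --
    used to build families of structurally related aglycones.
    """
    precursor = _uniform(rng, config.aglycone_mz_range)
    if core_mz is not None:
        jitter = rng.uniform(0.7, 1.3, size=len(core_mz))
        n_extra = config.n_unique_fragments
        mz = np.concatenate([core_mz, rng.uniform(50.0, precursor - 20.0, size=n_extra)])
        inten = np.concatenate([np.asarray(core_intensity) * jitter, rng.uniform(20.0, 100.0, size=n_extra)])
    else:
        lo, hi = config.n_fragments
        n = int(rng.integers(lo, hi + 1))
        mz = rng.uniform(50.0, precursor - 20.0, size=n)
        inten = rng.uniform(5.0, 100.0, size=n)
    inten = inten * (100.0 / inten.max())
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=precursor,
        polarity=config.polarity,
        mz=mz,
        intensity=inten,
        retention_time=_uniform(rng, config.rt_range),
    )


def _noise_peaks(rng: np.random.Generator, config: SynthConfig, precursor: float):
    lo, hi = config.noise_peaks
    n = int(rng.integers(lo, hi + 1))
    if n == 0:
        return np.empty(0), np.empty(0)
    return (
        rng.uniform(50.0, precursor - 5.0, size=n),
        rng.uniform(*config.noise_intensity_pct, size=n),
    )


def conjugate(
    aglycone: Spectrum,
    moiety: str,
    rng: np.random.Generator,
    config: SynthConfig,
    scan_id: str | None = None,
) -> Spectrum:
    """Conjugate an aglycone spectrum with a moiety.

    The precursor shifts by the exact moiety mass and the aglycone fragments
    are retained at jittered relative intensities (``fragment_jitter``),
    each dropped with probability ``fragment_dropout`` (at least three are
    always kept) -- conjugation changes fragmentation efficiency, so a
    conjugate spectrum resembles, but does not duplicate, its aglycone.  A
    fragment at the aglycone's precursor m/z yields the diagnostic neutral
    loss.  Glucuronides add the 113.0244/85.0295 product ions;
    galacturonides add them with probability ``decoy_product_prob`` and
    always add the 115.0038 discriminator; sulfates add nothing.
    """
    if moiety not in MOIETY_MASSES:
        raise ValueError(f"unknown moiety {moiety!r}; expected one of {sorted(MOIETY_MASSES)}")
    precursor = aglycone.precursor_mz + MOIETY_MASSES[moiety]
    keep = rng.uniform(size=aglycone.mz.size) >= config.fragment_dropout
    min_keep = min(3, aglycone.mz.size)
    if keep.sum() < min_keep:  # always retain the strongest fragments
        keep[np.argsort(aglycone.intensity)[-min_keep:]] = True
    frag_int = aglycone.intensity[keep] * rng.uniform(*config.fragment_jitter, size=int(keep.sum()))
    mz = [aglycone.mz[keep], np.array([aglycone.precursor_mz])]
    inten = [frag_int, np.array([_uniform(rng, config.nl_fragment_intensity_pct)])]

    def add(target_mz: float) -> None:
        mz.append(np.array([target_mz]))
        inten.append(np.array([_uniform(rng, config.diagnostic_intensity_pct)]))

    if moiety == "glucuronide":
        add(chem.FRAG_GLUCURONATE_113)
        add(chem.FRAG_GLUCURONATE_85)
    elif moiety == "galacturonide":
        if rng.uniform() < config.decoy_product_prob:
            add(chem.FRAG_GLUCURONATE_113)
            add(chem.FRAG_GLUCURONATE_85)
        add(chem.FRAG_GALACTURONIDE_115)
    nz_mz, nz_int = _noise_peaks(rng, config, precursor)
    mz.append(nz_mz)
    inten.append(nz_int)
    rt = aglycone.retention_time
    if rt is not None:
        rt = max(30.0, rt - float(rng.uniform(30.0, 120.0)))
    return Spectrum(
        scan_id=scan_id or f"{moiety}_of_{aglycone.scan_id}",
        precursor_mz=precursor,
        polarity=aglycone.polarity,
        mz=np.concatenate(mz),
        intensity=np.concatenate(inten),
        retention_time=rt,
        metadata={"parent_scan_id": aglycone.scan_id, "moiety": moiety},
    )


def _noise_spectrum(rng: np.random.Generator, config: SynthConfig, scan_id: str) -> Spectrum:
    precursor = float(rng.uniform(200.0, 700.0))
    lo, hi = config.n_fragments
    n = int(rng.integers(lo, hi + 1))
    inten = rng.uniform(5.0, 100.0, size=n)
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=precursor,
        polarity=config.polarity,
        mz=rng.uniform(50.0, precursor - 5.0, size=n),
        intensity=inten * (100.0 / inten.max()),
        retention_time=_uniform(rng, config.rt_range),
    )


def make_labeled_dataset(
    config: SynthConfig,
    class_counts: dict[str, int] | None = None,
) -> tuple[SpectrumCollection, pd.DataFrame]:
    """Generate spectra of every class with aligned ground-truth labels.

    ``class_counts`` overrides the per-class size (default
    ``config.n_per_class`` each).  Conjugates cycle over the generated
    aglycones as parents, so every conjugate's precursor delta to an
    existing aglycone is the exact moiety mass.  Labels carry ``scan_id``,
    ``true_class`` and ``parent_scan_id``.
    """
    counts = {c: config.n_per_class for c in CLASSES}
    if class_counts:
        unknown = set(class_counts) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class(es) {sorted(unknown)}")
        counts.update(class_counts)
    n_conjugates = counts["glucuronide"] + counts["galacturonide_decoy"] + counts["sulfate"]
    if n_conjugates and counts["aglycone"] == 0:
        raise ValueError("conjugate classes need at least one aglycone parent")

    rng = config.rng()
    spectra: list[Spectrum] = []
    rows: list[dict] = []

    aglycones = [
        make_aglycone_spectrum(rng, config, scan_id=f"aglycone_{i:04d}")
        for i in range(counts["aglycone"])
    ]
    for s in aglycones:
        spectra.append(s)
        rows.append({"scan_id": s.scan_id, "true_class": "aglycone", "parent_scan_id": ""})

    for cls, moiety in (
        ("glucuronide", "glucuronide"),
        ("galacturonide_decoy", "galacturonide"),
        ("sulfate", "sulfate"),
    ):
        for i in range(counts[cls]):
            parent = aglycones[i % len(aglycones)] if aglycones else None
            s = conjugate(parent, moiety, rng, config, scan_id=f"{cls}_{i:04d}")
            spectra.append(s)
            rows.append({"scan_id": s.scan_id, "true_class": cls, "parent_scan_id": parent.scan_id})

    for i in range(counts["noise"]):
        s = _noise_spectrum(rng, config, scan_id=f"noise_{i:04d}")
        spectra.append(s)
        rows.append({"scan_id": s.scan_id, "true_class": "noise", "parent_scan_id": ""})

    return SpectrumCollection(spectra), pd.DataFrame(rows, columns=["scan_id", "true_class", "parent_scan_id"])


def make_conjugate_network_dataset(
    config: SynthConfig,
) -> tuple[SpectrumCollection, pd.DataFrame, SpectrumCollection]:
    """Family-structured aglycones plus their glucuronides, with a library.

    Generates ``n_families`` families of ``family_size`` aglycones sharing a
    core fragment set (so within-family spectral similarity is high, as in
    real metabolite classes) and one glucuronide conjugate per aglycone.
    Returns ``(collection, pairs, library)`` where ``pairs`` lists each
    planted glucuronide:aglycone pair with the aglycone's compound name and
    ``library`` holds named copies of the aglycone spectra for annotation.
    """
    rng = config.rng()
    spectra: list[Spectrum] = []
    library: list[Spectrum] = []
    rows: list[dict] = []
    for f in range(config.n_families):
        core_mz = rng.uniform(60.0, 128.0, size=config.n_core_fragments)
        core_int = rng.uniform(30.0, 100.0, size=config.n_core_fragments)
        for i in range(config.family_size):
            name = f"fam{f}_agly{i}"
            agly = make_aglycone_spectrum(
                rng, config, scan_id=name, core_mz=core_mz, core_intensity=core_int
            )
            agly.metadata["compound_name"] = name
            glu = conjugate(agly, "glucuronide", rng, config, scan_id=f"fam{f}_glu{i}")
            spectra += [agly, glu]
            library.append(
                agly.copy(scan_id=f"lib_{name}", metadata={"compound_name": name})
            )
            rows.append(
                {
                    "glucuronide_scan_id": glu.scan_id,
                    "aglycone_scan_id": agly.scan_id,
                    "aglycone_name": name,
                }
            )
    pairs = pd.DataFrame(rows, columns=["glucuronide_scan_id", "aglycone_scan_id", "aglycone_name"])
    return SpectrumCollection(spectra), pairs, SpectrumCollection(library)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _lognormal_areas(
    rng: np.random.Generator,
    base_log10: np.ndarray,
    n_samples: int,
    sigma_log2: float,
) -> np.ndarray:
    base = 10.0 ** base_log10
    noise = 2.0 ** rng.normal(0.0, sigma_log2, size=(base.size, n_samples))
    return base[:, None] * noise


def make_planted_table(
    rng: np.random.Generator,
    n_features: int = 200,
    n_shifted: int = 20,
    n_per_group: int = 5,
    log2fc: float = 2.0,
    sigma_log2: float = 0.5,
    base_area_log10: tuple[float, float] = (5.0, 6.5),
    group_a: str = "GF",
    group_b: str = "FMT",
    matrix: str = "colon",
    direction: int = 1,
) -> tuple[FeatureTable, list[str]]:
    """Single-matrix table with ``n_shifted`` planted fold-change features.

    Areas are log-normal around a per-feature baseline (CV ~ 40% at the
    default ``sigma_log2``); planted features are shifted ``direction *
    log2fc`` log2 units in group B.  Returns the table and the planted
    feature ids.
    """
    fids = [f"{matrix}_feat_{i:04d}" for i in range(n_features)]
    base = rng.uniform(*base_area_log10, size=n_features)
    a = _lognormal_areas(rng, base, n_per_group, sigma_log2)
    b = _lognormal_areas(rng, base, n_per_group, sigma_log2)
    shifted = sorted(rng.choice(n_features, size=n_shifted, replace=False).tolist())
    b[shifted] *= 2.0 ** (direction * log2fc)
    mzs = rng.uniform(250.0, 700.0, size=n_features)
    rts = rng.uniform(60.0, 1200.0, size=n_features)
    sample_ids = [f"{matrix}_{group_a}_{i}" for i in range(n_per_group)] + [
        f"{matrix}_{group_b}_{i}" for i in range(n_per_group)
    ]
    features = pd.DataFrame(
        {"mz": mzs, "rt": rts}, index=pd.Index(fids, name="feature_id")
    )
    samples = pd.DataFrame(
        {
            "group": [group_a] * n_per_group + [group_b] * n_per_group,
            "matrix": matrix,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    areas = pd.DataFrame(np.hstack([a, b]), index=features.index, columns=sample_ids)
    table = FeatureTable(features=features, samples=samples, areas=areas)
    return table, [fids[i] for i in shifted]


#: Fraction of each matrix's features shifted by colonization, and the shift
#: direction in the colonized group; mirrors the dominant directions of the
#: germ-free vs FMT comparison (colon strongly depleted, serum and urine
#: enriched).
MATRIX_SHIFTS: dict[str, tuple[float, int]] = {
    "colon": (0.9, -1),
    "serum": (0.6, +1),
    "urine": (0.2, +1),
}


def make_feature_tables(
    config: SynthConfig,
    n_features: int = 200,
    n_per_group: int = 5,
    log2fc: float = 2.0,
    sigma_log2: float = 0.5,
    n_shared: int = 20,
) -> tuple[dict[str, FeatureTable], dict]:
    """Three-matrix (colon/serum/urine) tables with planted colonization shifts.

    Each matrix gets ``n_features`` glucuronidated features; a
    matrix-specific fraction (``MATRIX_SHIFTS``) is shifted ``log2fc`` log2
    units in the colonized group, downward in the colon and upward in serum
    and urine.  The first ``n_shared`` shifted features of each matrix
    represent the *same* conjugates across all three matrices: they share
    precursor m/z, retention time and a representative MS/MS spectrum, so
    cross-matrix matching recovers them as the planted triple overlap
    (colon depletion paired with urine/serum enrichment).

    Returns ``(tables, truth)`` with truth keys ``shifted`` (matrix ->
    feature ids), ``direction`` (matrix -> +/-1) and ``shared`` (matrix ->
    the feature ids of the cross-matrix conjugates, index-aligned).
    """
    rng = config.rng()
    tables: dict[str, FeatureTable] = {}
    truth: dict = {"shifted": {}, "direction": {}, "shared": {}}
    shared_mz = rng.uniform(250.0, 700.0, size=n_shared)
    shared_rt = rng.uniform(60.0, 1200.0, size=n_shared)
    shared_spectra = [
        make_aglycone_spectrum(rng, config, scan_id=f"shared_feat_{i:04d}")
        for i in range(n_shared)
    ]
    for matrix, (frac, direction) in MATRIX_SHIFTS.items():
        n_shifted = max(n_shared, int(round(frac * n_features)))
        table, shifted = make_planted_table(
            rng,
            n_features=n_features,
            n_shifted=n_shifted,
            n_per_group=n_per_group,
            log2fc=log2fc,
            sigma_log2=sigma_log2,
            matrix=matrix,
            direction=direction,
        )
        shared_ids = shifted[:n_shared]
        table.features.loc[shared_ids, "mz"] = shared_mz
        table.features.loc[shared_ids, "rt"] = shared_rt
        table.spectra = {
            fid: shared_spectra[i].copy(scan_id=f"{matrix}_{fid}")
            for i, fid in enumerate(shared_ids)
        }
        tables[matrix] = table
        truth["shifted"][matrix] = shifted
        truth["direction"][matrix] = direction
        truth["shared"][matrix] = shared_ids
    return tables, truth
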