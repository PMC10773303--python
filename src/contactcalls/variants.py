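"""Variant composition tables, sampling-effort summaries, and rater agreement.

Contact calls are manually sorted upstream into six structural variants
(typical, four_triangle, ladder_start, ladder_middle, ladder_multiple,
mix_alarm); the labels enter this package as metadata. This module tabulates
their per-city composition, summarizes sampling effort per park and city, and
computes Cohen's kappa for inter-observer agreement on categorical labels.

A fixture with the printed per-park call counts of the European monk parakeet
field survey (eight cities, 28 parks) ships with the package; see
:func:`load_sampling_effort`.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .synthetic import VARIANTS

__all__ = [
    "load_sampling_effort",
    "variant_proportions",
    "summarize_sampling",
    "cohen_kappa",
]

_KNOWN_VARIANTS = set(VARIANTS) | {"other"}


def load_sampling_effort() -> pd.DataFrame:
    """The shipped per-park sampling table (city, park, days, calls, nests)."""
    path = files("contactcalls.data").joinpath("sampling_effort.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


def variant_proportions(metadata: pd.DataFrame):
    """City x variant counts and row percentages.

    Calls without a variant label are excluded; their count is returned so the
    exclusion is visible. Unknown labels (outside the six variants plus
    ``other``) are an error.

    Returns (counts DataFrame, percentages DataFrame, n_unlabeled).
    """
    md = metadata
    if "variant" not in md.columns or "city" not in md.columns:
        raise ValueError("metadata needs 'city' and 'variant' columns")
    unlabeled = md["variant"].isna()
    labeled = md.loc[~unlabeled]
    unknown = sorted(set(labeled["variant"]) - _KNOWN_VARIANTS)
    if unknown:
        raise ValueError(f"unknown variant labels: {unknown}")
    counts = (
        labeled.groupby(["city", "variant"], sort=False).size().unstack(fill_value=0)
    )
    order = [v for v in VARIANTS if v in counts.columns] + [
        c for c in counts.columns if c not in VARIANTS
    ]
    counts = counts[order]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return counts, pct, int(unlabeled.sum())


def summarize_sampling(metadata: pd.DataFrame) -> dict:
    """Per-park and per-city call counts with medians and ranges.

    Accepts either raw per-call metadata (one row per call) or a pre-counted
    table with an ``n_calls`` column, as in the shipped sampling-effort
    fixture.
    """
    if metadata.empty:
        raise ValueError("empty metadata")
    if "n_calls" in metadata.columns:
        parks = metadata.groupby(["city", "park"], sort=False)["n_calls"].sum()
    else:
        parks = metadata.groupby(["city", "park"], sort=False).size()
    cities = parks.groupby(level="city").sum()
    return {
        "per_park": parks.rename("n_calls").reset_index(),
        "per_city": cities.rename("n_calls").reset_index(),
        "park_median": float(parks.median()),
        "park_range": (int(parks.min()), int(parks.max())),
        "n_parks": int(len(parks)),
        "city_median": float(cities.median()),
        "city_range": (int(cities.min()), int(cities.max())),
        "n_cities": int(len(cities)),
        "total_calls": int(parks.sum()),
    }


def cohen_kappa(labels_a, labels_b):
    """Unweighted Cohen's kappa and percent agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the raters' marginal label
    frequencies. When p_e == 1 (both raters constant and identical margins)
    the 0/0 case is resolved to kappa = 1 if the raters agree everywhere and
    0 otherwise.

    Returns (kappa, percent_agreement).
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty label sequences")
    p_o = float((a == b).mean())
    cats = sorted(set(a) | set(b))
    fa = a.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    fb = b.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    p_e = float((fa * fb).sum())
    if p_e == 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return float(kappa), 100.0 * p_o
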