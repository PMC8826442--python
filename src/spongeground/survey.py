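"""Per-category density, size-frequency, and areal summaries of image surveys.

An annotated survey is a long table (one row per observed sponge, plus one
placeholder row for images without sponges) as written by
:mod:`spongeground.synth`.  Densities are averaged unweighted across images
— each image is one sampling unit, matching how image surveys report
"average ± SD" — with a count-pooled (total count / total area) estimator
available as an alternative.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Observation",
    "SurveyImage",
    "CategorySummary",
    "SizeFrequency",
    "DensityPair",
    "images_from_table",
    "read_survey_csv",
    "image_density",
    "summarize_category",
    "size_frequency",
    "areal_upscale",
    "summaries_to_frame",
]


class Observation(NamedTuple):
    length_cm: float
    width_cm: float
    is_juvenile: bool


class DensityPair(NamedTuple):
    adult: float
    juvenile: float


@dataclass
class SurveyImage:
    """One annotated seafloor image."""

    image_id: str
    area_m2: float
    depth_m: float
    category: str
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError(f"image {self.image_id}: area must be positive")
        for obs in self.observations:
            if not obs.is_juvenile and not obs.length_cm > 0:
                raise ValueError(
                    f"image {self.image_id}: adult observations need positive lengths"
                )

    @property
    def adult_lengths(self) -> np.ndarray:
        return np.array(
            [o.length_cm for o in self.observations if not o.is_juvenile]
        )

    @property
    def n_adults(self) -> int:
        return sum(1 for o in self.observations if not o.is_juvenile)

    @property
    def n_juveniles(self) -> int:
        return sum(1 for o in self.observations if o.is_juvenile)


@dataclass
class SizeFrequency:
    median_cm: float
    q25_cm: float
    q75_cm: float
    min_cm: float
    max_cm: float
    n: int


@dataclass
class CategorySummary:
    category: str
    n_images: int
    density_mean: float
    density_sd: float
    juvenile_density_mean: float
    size_median: float
    size_q25: float
    size_q75: float
    sd_defined: bool = True
    biomass_C_mean: float | None = None  # g C m^-2, filled by the budget stage
    biomass_C_sd: float | None = None


def images_from_table(df: pd.DataFrame) -> list[SurveyImage]:
    """Parse a long observation table into :class:`SurveyImage` objects.

    Rows with NaN length and ``is_juvenile`` False are zero-count
    placeholders; juvenile rows carry NaN sizes by convention.
    """
    images: list[SurveyImage] = []
    for image_id, grp in df.groupby("image_id", sort=True):
        first = grp.iloc[0]
        obs = []
        for row in grp.itertuples(index=False):
            juvenile = bool(row.is_juvenile)
            if not juvenile and not np.isfinite(row.length_cm):
                continue  # placeholder row of an empty image
            obs.append(
                Observation(
                    float(row.length_cm) if np.isfinite(row.length_cm) else np.nan,
                    float(row.width_cm) if np.isfinite(row.width_cm) else np.nan,
                    juvenile,
                )
            )
        images.append(
            SurveyImage(
                image_id=str(image_id),
                area_m2=float(first["area_m2"]),
                depth_m=float(first["depth_m"]),
                category=str(first["category"]),
                observations=obs,
            )
        )
    return images


def read_survey_csv(path) -> list[SurveyImage]:
    """Read the CSV dialect written by the synthetic generator / CLI."""
    df = pd.read_csv(path, comment="#")
    return images_from_table(df)


def image_density(image: SurveyImage) -> DensityPair:
    """Adult and juvenile densities (ind m⁻²) of a single image."""
    return DensityPair(
        adult=image.n_adults / image.area_m2,
        juvenile=image.n_juveniles / image.area_m2,
    )


def summarize_category(
    images: Sequence[SurveyImage], estimator: str = "per_image"
) -> CategorySummary:
    """Density and size summary of one habitat category.

    ``estimator="per_image"`` averages per-image densities unweighted (the
    reporting convention for image surveys); ``"pooled"`` divides total
    counts by total imaged area.  Size quartiles pool all measured adults.
    """
    if not images:
        raise ValueError("cannot summarize an empty image list")
    cats = {im.category for im in images}
    if len(cats) > 1:
        raise ValueError(f"mixed categories in one summary: {sorted(cats)}")
    if estimator not in ("per_image", "pooled"):
        raise ValueError(f"unknown estimator {estimator!r}")

    dens = np.array([image_density(im).adult for im in images])
    juv = np.array([image_density(im).juvenile for im in images])
    if estimator == "pooled":
        total_area = sum(im.area_m2 for im in images)
        d_mean = sum(im.n_adults for im in images) / total_area
        j_mean = sum(im.n_juveniles for im in images) / total_area
    else:
        d_mean = float(dens.mean())
        j_mean = float(juv.mean())
    sd_defined = len(images) > 1
    d_sd = float(dens.std(ddof=1)) if sd_defined else 0.0

    lengths = np.concatenate([im.adult_lengths for im in images]) if images else np.empty(0)
    if lengths.size:
        q25, med, q75 = np.quantile(lengths, [0.25, 0.5, 0.75])  # type-7 default
    else:
        q25 = med = q75 = np.nan

    return CategorySummary(
        category=cats.pop(),
        n_images=len(images),
        density_mean=d_mean,
        density_sd=d_sd,
        juvenile_density_mean=j_mean,
        size_median=float(med),
        size_q25=float(q25),
        size_q75=float(q75),
        sd_defined=sd_defined,
    )


def size_frequency(images: Sequence[SurveyImage]) -> SizeFrequency:
    """Pooled adult size-frequency statistics (juveniles excluded).

    Quantiles use linear interpolation (numpy's default, the type-7
    convention).
    """
    lengths = (
        np.concatenate([im.adult_lengths for im in images])
        if images
        else np.empty(0)
    )
    if lengths.size == 0:
        raise ValueError("no measured adults to summarize")
    q25, med, q75 = np.quantile(lengths, [0.25, 0.5, 0.75])
    return SizeFrequency(
        median_cm=float(med),
        q25_cm=float(q25),
        q75_cm=float(q75),
        min_cm=float(lengths.min()),
        max_cm=float(lengths.max()),
        n=int(lengths.size),
    )


def areal_upscale(
    values: Mapping[str, float], areas: Mapping[str, float]
) -> float:
    """Area-weighted mean of a per-m² quantity across categories.

    ``Σ value_i · area_i / Σ area_i`` over the categories present in
    ``values``; a category without an area entry is an error.
    """
    missing = [c for c in values if c not in areas]
    if missing:
        raise KeyError(f"no area given for categories: {missing}")
    total = sum(areas[c] for c in values)
    if total <= 0:
        raise ValueError("total area must be positive")
    return sum(values[c] * areas[c] for c in values) / total


def summaries_to_frame(summaries: Iterable[CategorySummary]) -> pd.DataFrame:
    """Flatten summaries into a per-category DataFrame (CSV-friendly)."""
    rows = [vars(s).copy() for s in summaries]
    return pd.DataFrame(rows).set_index("category")
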