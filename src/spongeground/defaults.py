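"""Default study parameterization of the synthetic Arctic sponge ground.

Summit-level bulk-isotope means/SDs for the dominant sponge *Geodia parva*
and its candidate food sources, the habitat-category density gradient, the
community size distribution, and the default trophic-enrichment scenarios.
Summit codes: KM (southern, largest seamount), CM (central), NM (northern),
CS (saddle between KM and CM).

These constants define the study conditions the generators emulate; they are
inputs, not tunables.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

from .isotope import SourceDistribution, TrophicEnrichment
from .synth import CategorySpec, IsotopeGroupSpec, SizeDistributionSpec

__all__ = [
    "DEFAULT_SIZE_SPEC",
    "DEFAULT_CATEGORIES",
    "DEFAULT_AREAS_KM2",
    "DEFAULT_JUVENILE_DENSITY",
    "DEFAULT_IMAGE_COUNTS",
    "REFERENCE_ISOTOPE_GROUPS",
    "ADULT_GPARVA_GROUPS",
    "SOURCE_POOLS",
    "TEF_SCENARIOS",
    "pool_groups",
    "source_from_groups",
    "default_sources",
]

DEFAULT_SIZE_SPEC = SizeDistributionSpec(
    median_cm=17.0, q25_cm=11.0, q75_cm=25.0, min_cm=1.5, max_cm=110.0
)

# Density gradient across habitat categories (adult ind m^-2, across-image
# mean +- SD) and mapped areas.  Category "a" (occasional sponges on flank
# shelves) was never quantified by density and its area could not be mapped;
# a nominal sparse density and zero area keep it out of areal upscaling.
DEFAULT_CATEGORIES: tuple[CategorySpec, ...] = (
    CategorySpec("a", 0.1, 0.1, 0.0, (1000.0, 1300.0)),
    CategorySpec("b", 0.8, 0.7, 10.0, (950.0, 1200.0)),
    CategorySpec("c", 2.8, 1.1, 15.0, (750.0, 1000.0)),
    CategorySpec("d", 5.9, 1.7, 2.5, (585.0, 750.0)),
)

DEFAULT_AREAS_KM2: dict[str, float] = {c.label: c.area_km2 for c in DEFAULT_CATEGORIES}

#: small (<1 cm) juveniles, counted but not sized (ind m^-2)
DEFAULT_JUVENILE_DENSITY = 3.4

#: analyzed image counts per category in the reference survey
DEFAULT_IMAGE_COUNTS: dict[str, int] = {"a": 70, "b": 361, "c": 211, "d": 54}

# Summit-level bulk isotope reference values (permil; d13C vs VPDB, d15N vs
# air, D14C vs the 1950 standard with its 1-sigma analytical error).
REFERENCE_ISOTOPE_GROUPS: tuple[IsotopeGroupSpec, ...] = (
    IsotopeGroupSpec("G. parva (KM)", -18.40, 0.15, 8.43, 0.78, 7, -16.0, 6.0),
    IsotopeGroupSpec("G. parva (CM)", -19.33, 0.82, 7.52, 0.04, 1),
    IsotopeGroupSpec("G. parva (NM)", -18.62, 0.15, 7.72, 0.28, 5, -9.0, 6.0),
    IsotopeGroupSpec("G. parva (CS)", -18.34, 0.31, 8.29, 1.45, 2),
    IsotopeGroupSpec("G. parva juveniles (KM)", -18.87, 0.30, 6.59, 0.52, 5),
    IsotopeGroupSpec("G. hentscheli (KM)", -18.19, 0.22, 8.16, 0.51, 4),
    IsotopeGroupSpec("G. hentscheli (NM)", -18.26, 0.22, 7.52, 0.51, 3),
    IsotopeGroupSpec("S. rhaphidiophora (KM)", -18.28, 0.36, 8.42, 0.28, 3),
    IsotopeGroupSpec("siboglinid tubes (KM)", -19.77, 0.29, 8.91, 1.02, 3),
    IsotopeGroupSpec("siboglinid tubes (NM)", -19.20, 0.74, 9.31, 0.31, 1, -213.0, 7.0),
    IsotopeGroupSpec("sediment (KM)", -21.42, 1.46, 5.87, 0.77, 6, -527.0, 2.0),
    IsotopeGroupSpec("sediment (CM)", -21.81, 0.51, 6.01, 1.28, 3),
    IsotopeGroupSpec("sediment (NM)", -23.04, 1.25, 4.84, 1.96, 3, -436.0, 4.0),
    IsotopeGroupSpec("sediment (CS)", -21.57, 0.58, 5.65, 1.13, 3),
    IsotopeGroupSpec("POM (KM)", -27.43, None, 5.55, None, 1, -36.0, None),
    IsotopeGroupSpec("POM (CM)", -29.51, None, 4.17, None, 1),
    IsotopeGroupSpec("POM (NM)", -27.88, None, 4.38, None, 1),
    IsotopeGroupSpec("POM (CS)", -26.98, None, 4.99, None, 1),
    IsotopeGroupSpec("DOM", -22.3, None, 4.6, None, 1, -406.0, None),
    IsotopeGroupSpec("bryozoans/hydrozoans (NM)", -12.12, 3.34, 10.37, 0.60, 1, -245.0, 2.0),
)

ADULT_GPARVA_GROUPS: tuple[str, ...] = (
    "G. parva (KM)",
    "G. parva (CM)",
    "G. parva (NM)",
    "G. parva (CS)",
)

#: pooling of summit-level groups into mixing-model end-members
SOURCE_POOLS: dict[str, tuple[str, ...]] = {
    "siboglinid tubes": ("siboglinid tubes (KM)", "siboglinid tubes (NM)"),
    "POM": ("POM (KM)", "POM (CM)", "POM (NM)", "POM (CS)"),
    "sediment": ("sediment (KM)", "sediment (CM)", "sediment (NM)", "sediment (CS)"),
    "DOM": ("DOM",),
}

#: default three-source end-member set of the headline mixing run
DEFAULT_SOURCE_NAMES: tuple[str, ...] = ("siboglinid tubes", "POM", "sediment")

# Trophic-enrichment scenarios (permil): "microbial" reflects substantial
# symbiont-mediated processing (low 15N enrichment); "classical" is the
# standard metazoan predator value.
TEF_SCENARIOS: dict[str, TrophicEnrichment] = {
    "microbial": TrophicEnrichment(
        means={"d13C": 0.5, "d15N": 1.5}, sds={"d13C": 0.5, "d15N": 0.5}
    ),
    "classical": TrophicEnrichment(
        means={"d13C": 0.5, "d15N": 3.5}, sds={"d13C": 0.5, "d15N": 0.5}
    ),
}


def _registry(
    groups: Iterable[IsotopeGroupSpec] | None,
) -> Mapping[str, IsotopeGroupSpec]:
    groups = REFERENCE_ISOTOPE_GROUPS if groups is None else tuple(groups)
    return {g.group: g for g in groups}


def pool_groups(
    names: Sequence[str],
    pooled_name: str,
    groups: Iterable[IsotopeGroupSpec] | None = None,
) -> IsotopeGroupSpec:
    """Pool summit-level groups into one spec by exact sample pooling.

    The pooled mean is the n-weighted mean; the pooled variance combines
    within-group sums of squares and between-group spread so it equals the
    sample variance of the concatenated underlying samples.  Groups of n = 1
    contribute no within-group term.
    """
    reg = _registry(groups)
    members = [reg[name] for name in names]
    n_total = sum(g.n for g in members)

    def _pool(means, sds, ns):
        mean = sum(n * m for n, m in zip(ns, means)) / n_total
        if n_total < 2:
            return mean, None
        ss = sum((n - 1) * (s or 0.0) ** 2 for n, s in zip(ns, sds))
        ss += sum(n * (m - mean) ** 2 for n, m in zip(ns, means))
        return mean, math.sqrt(ss / (n_total - 1))

    ns = [g.n for g in members]
    c_mean, c_sd = _pool([g.d13C_mean for g in members], [g.d13C_sd for g in members], ns)
    n_mean, n_sd = _pool([g.d15N_mean for g in members], [g.d15N_sd for g in members], ns)
    return IsotopeGroupSpec(pooled_name, c_mean, c_sd, n_mean, n_sd, n_total)


def source_from_groups(
    names: Sequence[str],
    pooled_name: str,
    groups: Iterable[IsotopeGroupSpec] | None = None,
) -> SourceDistribution:
    """Build a mixing-model end-member from pooled summit groups."""
    pooled = pool_groups(names, pooled_name, groups)
    return SourceDistribution(
        name=pooled_name,
        means={"d13C": pooled.d13C_mean, "d15N": pooled.d15N_mean},
        sds={"d13C": pooled.d13C_sd or 0.0, "d15N": pooled.d15N_sd or 0.0},
    )


def default_sources(
    names: Sequence[str] = DEFAULT_SOURCE_NAMES,
) -> list[SourceDistribution]:
    """The default end-member set, pooled across summits."""
    return [source_from_groups(SOURCE_POOLS[n], n) for n in names]
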