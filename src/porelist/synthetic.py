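"""Seeded generator of synthetic occurrence-record datasets with known
ground truth.

The generator emulates the statistical structure a regional polypore
checklist analysis assumes, so every downstream stage can be tested
without fungarium data:

* a species pool (default ~200 species) with a log-series abundance
  distribution, so that a realistic share of species end up as
  singletons and doubletons at survey effort;
* habitat-structured occurrence: each species carries per-site-type
  affinities and host preferences organised in phylogenetic host blocks
  (conifers / soft deciduous / hardwoods);
* a fixed-effort plot-survey protocol: species draws proportional to
  abundance x habitat affinity, with hard caps of 10 records per species
  per plot and 150 records per plot, truncating in seeded draw order;
* a casual-collection stream whose draws are additionally weighted by a
  per-species detectability multiplier;
* a configurable fraction of species constructed as single-host or
  single-habitat specialists, recorded in a machine-readable truth table.

Decay-stage and woody-fraction assignment are independent of habitat
given the species - a stated simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from porelist.records import (
    AgeClass,
    DatasetId,
    DecayStage,
    HabitatKey,
    OccurrenceRecord,
    SpecialHabitat,
    SubstrateFraction,
    TreeClass,
    DEFAULT_SITE_TYPE_GROUPS,
)

__all__ = [
    "SpeciesProfile", "SurveyDesign", "DEFAULT_HOST_BLOCKS",
    "sample_species_pool", "simulate_survey", "ground_truth",
    "default_survey_design",
]

#: Host taxa grouped into phylogenetic blocks; aggregate taxa (Betula spp.,
#: Salix spp., Ulmus spp.) follow checklist-table granularity.
DEFAULT_HOST_BLOCKS: Mapping[str, tuple[str, ...]] = {
    "conifer": ("Picea abies", "Pinus sylvestris", "Juniperus communis"),
    "soft_deciduous": ("Populus tremula", "Betula spp.", "Alnus incana",
                       "Alnus glutinosa", "Salix spp."),
    "hardwood": ("Quercus robur", "Fraxinus excelsior", "Ulmus spp.",
                 "Acer platanoides", "Tilia cordata"),
}

#: Relative availability of host taxa encountered in plots of each
#: tree-composition class (rough hemiboreal forest composition).
HOST_AVAILABILITY: Mapping[TreeClass, Mapping[str, float]] = {
    TreeClass.picea: {
        "Picea abies": 0.55, "Betula spp.": 0.15, "Populus tremula": 0.08,
        "Alnus incana": 0.08, "Pinus sylvestris": 0.06, "Salix spp.": 0.02,
        "Alnus glutinosa": 0.02, "Quercus robur": 0.01,
        "Fraxinus excelsior": 0.01, "Ulmus spp.": 0.005,
        "Acer platanoides": 0.01, "Tilia cordata": 0.005,
        "Juniperus communis": 0.01,
    },
    TreeClass.pinus: {
        "Pinus sylvestris": 0.68, "Betula spp.": 0.16, "Picea abies": 0.10,
        "Populus tremula": 0.02, "Alnus incana": 0.01, "Salix spp.": 0.01,
        "Juniperus communis": 0.02,
    },
    TreeClass.deciduous: {
        "Betula spp.": 0.28, "Populus tremula": 0.18, "Alnus incana": 0.14,
        "Alnus glutinosa": 0.12, "Salix spp.": 0.06, "Quercus robur": 0.08,
        "Fraxinus excelsior": 0.05, "Ulmus spp.": 0.03,
        "Acer platanoides": 0.03, "Tilia cordata": 0.03,
    },
}

#: Host availability in the pooled special habitats (old deciduous trees
#: dominate parks and wooded meadows; bog and heath forests are pine land).
SPECIAL_AVAILABILITY: Mapping[SpecialHabitat, TreeClass] = {
    SpecialHabitat.park: TreeClass.deciduous,
    SpecialHabitat.wooded_meadow: TreeClass.deciduous,
    SpecialHabitat.bog_forest: TreeClass.pinus,
    SpecialHabitat.heath_forest: TreeClass.pinus,
}

_FRACTIONS = (SubstrateFraction.coarse_fallen, SubstrateFraction.snag_stump,
              SubstrateFraction.fwd, SubstrateFraction.live_tree)
_DECAY_STAGES = (DecayStage.I, DecayStage.II, DecayStage.III,
                 DecayStage.IV, DecayStage.V)


@dataclass
class SpeciesProfile:
    species_id: str
    relative_abundance: float
    habitat_affinity: dict[str, float]       # keyed by site group / special habitat
    host_preference: dict[str, float]        # per-host multiplier, >= 0
    decay_profile: np.ndarray                # simplex over early/medium/late
    fraction_profile: np.ndarray             # simplex over the four fractions
    detectability: float                     # (0, 1] casual-stream multiplier
    host_block: str                          # block carrying most preference
    specialist_axis: Optional[str] = None    # "host" or "habitat"
    specialist_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.relative_abundance <= 0:
            raise ValueError("relative abundance must be positive")
        if not 0 < self.detectability <= 1:
            raise ValueError("detectability must lie in (0, 1]")
        for simplex, k in ((self.decay_profile, 3), (self.fraction_profile, 4)):
            if len(simplex) != k or abs(float(np.sum(simplex)) - 1.0) > 1e-9:
                raise ValueError("profile must be a simplex")
        if any(v < 0 for v in self.habitat_affinity.values()) or \
           any(v < 0 for v in self.host_preference.values()):
            raise ValueError("multipliers must be non-negative")

    @property
    def specialist(self) -> bool:
        return self.specialist_axis is not None


@dataclass
class SurveyDesign:
    plots: list[tuple[str, HabitatKey]]
    per_species_cap: int = 10
    per_plot_cap: int = 150
    mean_attempts: float = 200.0   # expected candidate draws per plot (pre-cap)
    casual_effort: float = 600.0   # expected casual-stream records
    survey_years: tuple[int, int] = (2005, 2016)
    casual_years: tuple[int, int] = (2005, 2018)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_species_cap <= 0 or self.per_plot_cap <= 0:
            raise ValueError("caps must be positive")


def default_survey_design(n_plots: int = 60, casual_effort: float = 600.0,
                          seed: int = 0) -> SurveyDesign:
    """A plot layout cycling through common site-type groups, tree
    classes and age classes (old stands in a realistic minority)."""
    groups = ("meso_eutrophic", "dry_boreal", "eutrophic_paludifying",
              "eutrophic_boreo_nemoral", "drained_peatland", "fresh_boreal")
    trees = (TreeClass.picea, TreeClass.pinus, TreeClass.deciduous)
    plots = []
    for i in range(n_plots):
        key = HabitatKey(site_type_group=groups[i % len(groups)],
                         tree_class=trees[(i // len(groups)) % len(trees)],
                         age_class=AgeClass.old if i % 4 == 0 else AgeClass.other)
        plots.append((f"plot{i + 1:03d}", key))
    return SurveyDesign(plots=plots, casual_effort=casual_effort, seed=seed)


def _dirichlet(rng: np.random.Generator, alpha: Sequence[float]) -> np.ndarray:
    x = rng.dirichlet(np.asarray(alpha, dtype=float))
    return x / x.sum()


def sample_species_pool(S: int = 200, theta: float = 0.995,
                        block_structure: Mapping[str, Sequence[str]] = DEFAULT_HOST_BLOCKS,
                        specialist_fraction: float = 0.2,
                        site_type_groups: Sequence[str] = DEFAULT_SITE_TYPE_GROUPS,
                        seed: int = 0) -> list[SpeciesProfile]:
    """Draw a species pool with log-series abundances and block-structured
    host preferences.

    *theta* is the log-series shape parameter in (0, 1); larger values
    give a more skewed abundance distribution (more rare species).
    ``round(S * specialist_fraction)`` species are constructed as strict
    single-host or single-habitat specialists and flagged in the profile.
    """
    if S < 2:
        raise ValueError("need at least two species")
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    abundances = stats.logser.rvs(theta, size=S, random_state=rng).astype(float)
    abundances /= abundances.sum()

    hosts = [h for block in block_structure.values() for h in block]
    block_of = {h: b for b, block in block_structure.items() for h in block}
    blocks = list(block_structure)
    habitat_keys = list(site_type_groups) + [s.value for s in SpecialHabitat]

    n_specialists = int(round(S * specialist_fraction))
    specialist_idx = set(rng.choice(S, size=n_specialists, replace=False).tolist())

    pool: list[SpeciesProfile] = []
    for i in range(S):
        species_id = f"sp{i + 1:03d}"
        # host preferences concentrated in one phylogenetic block
        home_block = blocks[int(rng.integers(len(blocks)))]
        pref = {}
        for h in hosts:
            base = rng.gamma(2.0, 1.0)
            pref[h] = base * (4.0 if block_of[h] == home_block else 0.15)
        # habitat affinities: a couple of preferred site groups
        affinity = {k: float(rng.gamma(1.0, 0.3)) for k in habitat_keys}
        preferred = rng.choice(len(site_type_groups),
                               size=min(3, len(site_type_groups)), replace=False)
        for j in preferred:
            affinity[site_type_groups[j]] += float(rng.gamma(3.0, 1.0))

        specialist_axis = specialist_category = None
        if i in specialist_idx:
            if rng.random() < 0.5:
                # single-host specialist: all preference on one host
                target = hosts[int(rng.integers(len(hosts)))]
                pref = {h: 0.0 for h in hosts}
                pref[target] = 30.0
                home_block = block_of[target]
                specialist_axis, specialist_category = "host", target
            else:
                target_group = site_type_groups[int(rng.integers(len(site_type_groups)))]
                affinity = {k: 0.01 for k in habitat_keys}
                affinity[target_group] = 10.0
                specialist_axis, specialist_category = "habitat", target_group

        decay = _dirichlet(rng, (2.0, 2.0, 2.0))
        fraction = _dirichlet(rng, (4.0, 2.0, 2.0, 0.5))
        pool.append(SpeciesProfile(
            species_id=species_id,
            relative_abundance=float(abundances[i]),
            habitat_affinity=affinity,
            host_preference=pref,
            decay_profile=decay,
            fraction_profile=fraction,
            detectability=float(rng.uniform(0.05, 1.0)),
            host_block=home_block,
            specialist_axis=specialist_axis,
            specialist_category=specialist_category,
        ))
    return pool


def ground_truth(pool: Sequence[SpeciesProfile]) -> dict:
    """Machine-readable truth tables for recovery tests: specialist
    flags, habitat-affinity ranking, and host-block membership."""
    return {
        "specialists": {
            p.species_id: {"axis": p.specialist_axis,
                           "category": p.specialist_category}
            for p in pool if p.specialist
        },
        "host_block": {p.species_id: p.host_block for p in pool},
        "preferred_habitats": {
            p.species_id: sorted(p.habitat_affinity,
                                 key=p.habitat_affinity.get, reverse=True)[:3]
            for p in pool
        },
    }


def _plot_host_availability(key: HabitatKey) -> Mapping[str, float]:
    if key.special_habitat is not None:
        return HOST_AVAILABILITY[SPECIAL_AVAILABILITY[key.special_habitat]]
    return HOST_AVAILABILITY[key.tree_class]


def _habitat_weight(profile: SpeciesProfile, key: HabitatKey,
                    avail: Mapping[str, float]) -> float:
    if key.special_habitat is not None:
        site_aff = profile.habitat_affinity.get(key.special_habitat.value, 0.0)
    else:
        site_aff = profile.habitat_affinity.get(key.site_type_group, 0.0)
    host_match = sum(a * profile.host_preference.get(h, 0.0)
                     for h, a in avail.items())
    return profile.relative_abundance * site_aff * host_match


def _draw_record(rng: np.random.Generator, profile: SpeciesProfile,
                 avail: Mapping[str, float], year: int,
                 dataset_id: DatasetId, plot_id: Optional[str],
                 key: Optional[HabitatKey]) -> OccurrenceRecord:
    hosts = list(avail)
    w = np.array([avail[h] * profile.host_preference.get(h, 0.0) for h in hosts])
    if w.sum() <= 0:
        # none of the locally available hosts suits the species (casual
        # records of strict specialists): fall back to the species' own
        # host preference - collectors find the species where its host is
        hosts = [h for h, p in profile.host_preference.items() if p > 0]
        w = np.array([profile.host_preference[h] for h in hosts])
    host = hosts[int(rng.choice(len(hosts), p=w / w.sum()))]
    frac = _FRACTIONS[int(rng.choice(4, p=profile.fraction_profile))]
    decay: Optional[DecayStage] = None
    if frac is not SubstrateFraction.live_tree:
        # decay class -> a concrete stage within the class
        cls = int(rng.choice(3, p=profile.decay_profile))
        stage_options = ((DecayStage.I, DecayStage.II), (DecayStage.III,),
                         (DecayStage.IV, DecayStage.V))[cls]
        decay = stage_options[int(rng.integers(len(stage_options)))]
    return OccurrenceRecord(
        species_id=profile.species_id, dataset_id=dataset_id, year=year,
        plot_id=plot_id,
        site_type_group=key.site_type_group if key else None,
        tree_class=key.tree_class if key else None,
        age_class=key.age_class if key else None,
        host_taxon=host, substrate_fraction=frac, decay_raw=decay,
        special_habitat=key.special_habitat if key else None,
    )


def simulate_survey(pool: Sequence[SpeciesProfile],
                    design: SurveyDesign) -> list[OccurrenceRecord]:
    """Simulate the survey protocol over the design's plots plus the
    casual-collection stream.

    Per plot, candidate draws arrive in seeded order with species
    probabilities proportional to relative abundance x habitat affinity;
    draws beyond the per-species cap (default 10, "first ten records")
    are discarded and the plot stops at the per-plot cap (default 150).
    Casual draws are weighted additionally by species detectability and
    carry no plot; they are assigned a special habitat or a stand triple
    drawn from the design's plot habitats.
    """
    rng = np.random.default_rng(design.seed)
    records: list[OccurrenceRecord] = []

    for plot_id, key in design.plots:
        avail = _plot_host_availability(key)
        weights = np.array([_habitat_weight(p, key, avail) for p in pool])
        if weights.sum() <= 0:
            continue
        prob = weights / weights.sum()
        n_attempts = int(rng.poisson(design.mean_attempts))
        per_species: dict[str, int] = {}
        n_plot = 0
        for sp_idx in rng.choice(len(pool), size=n_attempts, p=prob):
            if n_plot >= design.per_plot_cap:
                break
            profile = pool[int(sp_idx)]
            if per_species.get(profile.species_id, 0) >= design.per_species_cap:
                continue
            year = int(rng.integers(design.survey_years[0],
                                    design.survey_years[1] + 1))
            records.append(_draw_record(rng, profile, avail, year,
                                        DatasetId.IIc, plot_id, key))
            per_species[profile.species_id] = per_species.get(profile.species_id, 0) + 1
            n_plot += 1

    # casual stream: detectability-biased, no fixed plots
    n_casual = int(rng.poisson(design.casual_effort))
    w = np.array([p.relative_abundance * p.detectability for p in pool])
    if n_casual and w.sum() > 0:
        prob = w / w.sum()
        specials = list(SpecialHabitat)
        plot_keys = [key for _, key in design.plots]
        for sp_idx in rng.choice(len(pool), size=n_casual, p=prob):
            profile = pool[int(sp_idx)]
            if plot_keys and rng.random() < 0.7:
                key = plot_keys[int(rng.integers(len(plot_keys)))]
            else:
                key = HabitatKey(special_habitat=specials[int(rng.integers(len(specials)))])
            avail = _plot_host_availability(key)
            year = int(rng.integers(design.casual_years[0],
                                    design.casual_years[1] + 1))
            records.append(_draw_record(rng, profile, avail, year,
                                        DatasetId.IIIa, None, key))
    return records
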