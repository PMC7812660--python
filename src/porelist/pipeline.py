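"""End-to-end pipeline orchestration from a single config.

Stages run in order records -> checklist -> substrate -> assemblage; a
manifest JSON lists every output file with a SHA-256 content hash, so
identical config + seed yields identical manifests (bit-reproducible
runs).  Each stage logs one line with its parameters and row counts.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from porelist import community, richness, substrate
from porelist.records import (
    OccurrenceRecord, band_count, read_records, recode_decay, write_records,
)
from porelist.synthetic import (
    default_survey_design, ground_truth, sample_species_pool, simulate_survey,
)

logger = logging.getLogger("porelist")

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline",
           "export_species_table", "load_config"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


#: The packaged synthetic study configuration: a ~200-species pool with
#: log-series abundances, 60 fixed-effort plots and a casual stream of
#: ~600 records (about 10% of the total, as in regional checklist data).
DEFAULT_CONFIG: Mapping[str, Any] = {
    "synthetic": {"S": 200, "theta": 0.995, "specialist_fraction": 0.2,
                  "n_plots": 60, "casual_effort": 600.0, "seed": 7},
    "params": {"chao_variant": "classic", "permutations": 999,
               "n_starts": 10, "current_year": 2019, "seed": 7},
}


def default_config(seed: Optional[int] = None) -> "PipelineConfig":
    """The packaged synthetic pipeline configuration (optionally reseeded)."""
    import copy

    raw = copy.deepcopy(dict(DEFAULT_CONFIG))
    return PipelineConfig.from_dict(raw, seed_override=seed)


_SYNTH_KEYS = {"S", "theta", "specialist_fraction", "n_plots",
               "casual_effort", "seed"}
_INPUT_KEYS = {"records_csv", "ledger_csv"}
_STAGE_KEYS = {"checklist", "substrate", "assemblage"}
_PARAM_KEYS = {"chao_variant", "current_year", "extinction_horizon",
               "post_cutoff_year", "permutations", "n_starts",
               "band_threshold", "systematic_min", "host_min_records",
               "seed"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of a synthetic-generation block or an input block must
    be present; every random stage needs an explicit seed.
    """

    synthetic: Optional[dict] = None
    input: Optional[dict] = None
    stages: dict = field(default_factory=lambda: {
        "checklist": True, "substrate": True, "assemblage": True})
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any],
                  seed_override: Optional[int] = None) -> "PipelineConfig":
        known = {"synthetic", "input", "stages", "params"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        synth = dict(raw.get("synthetic") or {}) or None
        inp = dict(raw.get("input") or {}) or None
        if (synth is None) == (inp is None):
            raise ConfigError("config needs exactly one of 'synthetic' or 'input'")
        stages = {**{"checklist": True, "substrate": True, "assemblage": True},
                  **(raw.get("stages") or {})}
        params = dict(raw.get("params") or {})
        for block, keys, label in ((synth, _SYNTH_KEYS, "synthetic"),
                                   (inp, _INPUT_KEYS, "input"),
                                   (stages, _STAGE_KEYS, "stages"),
                                   (params, _PARAM_KEYS, "params")):
            if block:
                bad = set(block) - keys
                if bad:
                    raise ConfigError(f"unknown {label} keys: {sorted(bad)}")
        if synth is not None:
            if seed_override is not None:
                synth["seed"] = seed_override
            if "seed" not in synth:
                raise ConfigError("synthetic generation requires an explicit seed")
        if seed_override is not None:
            params["seed"] = seed_override
        if "seed" not in params:
            if synth is not None:
                params["seed"] = synth["seed"]
            else:
                raise ConfigError("params.seed is required for analysis stages")
        return cls(synthetic=synth, input=inp, stages=stages, params=params)


def load_config(path: str | Path,
                seed_override: Optional[int] = None) -> PipelineConfig:
    """Load a YAML or JSON pipeline config file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return PipelineConfig.from_dict(raw, seed_override=seed_override)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def export_species_table(records: Sequence[OccurrenceRecord],
                         band_threshold: int = 100,
                         systematic_min: int = 25) -> pd.DataFrame:
    """Checklist-style per-species export: banded record counts per
    source group (historical I / systematic II / casual III) and, for
    species with at least *systematic_min* systematic records,
    percentage breakdowns of the systematic sample by stand age, host
    taxon, woody fraction and decay class (integer percentages, half-up).
    """
    by_species: dict[str, list[OccurrenceRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)

    def pct_block(recs: list[OccurrenceRecord], value_fn) -> str:
        values = [v for v in (value_fn(r) for r in recs) if v is not None]
        if not values:
            return ""
        counts = pd.Series(values).value_counts().sort_index()
        total = counts.sum()
        exact = 100.0 * counts / total
        # largest-remainder apportionment: integer percentages that sum
        # to exactly 100 (plain rounding can drift with many categories)
        floors = np.floor(exact).astype(int)
        remainder = int(100 - floors.sum())
        order = (exact - floors).sort_values(ascending=False).index
        pct = floors.copy()
        for k in order[:remainder]:
            pct[k] += 1
        return ";".join(f"{k}:{pct[k]}" for k in counts.index)

    rows = []
    for species in sorted(by_species):
        recs = by_species[species]
        groups = {"I": 0, "II": 0, "III": 0}
        for r in recs:
            groups[r.dataset_id.source_group] += 1
        systematic = [r for r in recs if r.dataset_id.systematic]
        row = {
            "species_id": species,
            "records_I": str(band_count(groups["I"], band_threshold)),
            "records_II": str(band_count(groups["II"], band_threshold)),
            "records_III": str(band_count(groups["III"], band_threshold)),
        }
        if len(systematic) >= systematic_min:
            row["age_pct"] = pct_block(
                systematic, lambda r: r.age_class.value if r.age_class else None)
            row["host_pct"] = pct_block(systematic, lambda r: r.host_taxon)
            row["fraction_pct"] = pct_block(
                systematic,
                lambda r: r.substrate_fraction.value if r.substrate_fraction else None)
            row["decay_pct"] = pct_block(
                systematic,
                lambda r: (recode_decay(r.decay_raw).value
                           if r.decay_raw is not None else None))
        else:
            row.update(age_pct="", host_pct="", fraction_pct="", decay_pct="")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage runners

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Writer:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.outputs: dict[str, str] = {}

    def text(self, name: str, content: str) -> None:
        path = self.out_dir / name
        path.write_text(content)
        self.outputs[name] = _sha256(path)

    def json(self, name: str, obj: Any) -> None:
        self.text(name, json.dumps(obj, indent=2, sort_keys=True) + "\n")

    def frame(self, name: str, df: pd.DataFrame, index: bool = True) -> None:
        buf = io.StringIO()
        df.to_csv(buf, index=index, lineterminator="\n")
        self.text(name, buf.getvalue())


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the configured stages and write a manifest.

    Returns the manifest mapping; on stage failure, partial outputs are
    retained, the manifest carries a failure marker, and the exception
    propagates after the manifest is written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    writer = _Writer(out)
    manifest: dict[str, Any] = {"stages_run": [], "outputs": writer.outputs}
    params = config.params
    failed: Optional[str] = None

    try:
        # --- records stage ------------------------------------------------
        if config.synthetic is not None:
            s = config.synthetic
            pool = sample_species_pool(
                S=int(s.get("S", 200)), theta=float(s.get("theta", 0.995)),
                specialist_fraction=float(s.get("specialist_fraction", 0.2)),
                seed=int(s["seed"]))
            design = default_survey_design(
                n_plots=int(s.get("n_plots", 60)),
                casual_effort=float(s.get("casual_effort", 600.0)),
                seed=int(s["seed"]))
            records = simulate_survey(pool, design)
            truth = ground_truth(pool)
            buf = io.StringIO()
            write_records(records, buf)
            writer.text("records.csv", buf.getvalue())
            writer.json("truth.json", truth)
            logger.info("simulate: S=%d plots=%d records=%d seed=%d",
                        len(pool), len(design.plots), len(records), s["seed"])
            ledger = []
        else:
            with open(config.input["records_csv"]) as fh:
                records, report = read_records(
                    fh, current_year=int(params.get("current_year", 2019)))
            writer.text("read_report.txt", report.log_text())
            logger.info("read: accepted=%d rejected=%d",
                        report.accepted, report.rejected)
            ledger_path = config.input.get("ledger_csv")
            ledger = []
            if ledger_path:
                with open(ledger_path) as fh:
                    ledger = richness.read_ledger_csv(fh)
        manifest["stages_run"].append("records")
        manifest["n_records"] = len(records)

        # --- checklist stage ---------------------------------------------
        if config.stages.get("checklist", True):
            failed = "checklist"
            variant = params.get("chao_variant", "classic")
            counts, summary = richness.tally_frequencies(records)
            summary.S_chao = richness.chao1(summary.S_obs, summary.f1,
                                            summary.f2, variant)
            summary.estimator_variant = richness.ChaoVariant(variant)
            current_year = int(params.get("current_year", 2019))
            last_year = {}
            for rec in records:
                last_year[rec.species_id] = max(
                    last_year.get(rec.species_id, 0), rec.year)
            extinct = richness.flag_regionally_extinct(
                last_year, current_year,
                horizon=int(params.get("extinction_horizon", 50)))
            no_recent = richness.records_since(
                records, int(params.get("post_cutoff_year", 2004)))
            checklist_out = {
                "S_obs": summary.S_obs, "f1": summary.f1, "f2": summary.f2,
                "S_chao": round(summary.S_chao, 2),
                "S_chao_reported": _round_half_up(summary.S_chao),
                "estimator_variant": variant,
                "regionally_extinct": extinct,
                "no_recent_records": no_recent,
            }
            if ledger:
                base = sorted(counts)
                rep = richness.apply_ledger(base, ledger, strict=False)
                checklist_out["ledger"] = {
                    "n_base": len(base), "n_accepted": len(rep.accepted),
                    "n_merged": len(rep.merged),
                    "n_excluded_unsupported": len(rep.excluded_unsupported),
                    "n_excluded_misidentified": len(rep.excluded_misidentified),
                    "n_added": len(rep.added),
                }
            writer.json("checklist.json", checklist_out)
            writer.frame("species_counts.csv",
                         pd.Series(counts).sort_index().rename("n_records")
                         .to_frame())
            logger.info("checklist: S_obs=%d f1=%d f2=%d chao=%.2f",
                        summary.S_obs, summary.f1, summary.f2, summary.S_chao)
            manifest["stages_run"].append("checklist")

        # --- substrate stage ----------------------------------------------
        if config.stages.get("substrate", True):
            failed = "substrate"
            host_table = substrate.build_association_table(records, "host_taxon")
            writer.frame("association_host.csv", host_table.counts)
            results = substrate.classify_table(host_table)
            writer.frame("classification_host.csv",
                         substrate.classification_frame(results), index=False)
            hr = substrate.host_range_summary(
                host_table, min_records=int(params.get("host_min_records", 10)))
            writer.frame("host_range.csv", hr, index=False)
            pa = substrate.host_similarity_input(host_table)
            writer.frame("host_presence_absence.csv", pa)
            dendro = substrate.cluster_hosts(pa)
            writer.text("hosts.nwk", dendro.to_newick() + "\n")
            for axis, name in (("substrate_fraction", "fraction"),
                               ("decay_class", "decay")):
                try:
                    t = substrate.build_association_table(records, axis)
                except ValueError:
                    continue
                writer.frame(f"association_{name}.csv", t.counts)
            table2 = export_species_table(
                records, band_threshold=int(params.get("band_threshold", 100)),
                systematic_min=int(params.get("systematic_min", 25)))
            writer.frame("species_table.csv", table2, index=False)
            logger.info("substrate: hosts=%d classified_pairs=%d",
                        host_table.counts.shape[1], len(results))
            manifest["stages_run"].append("substrate")

        # --- assemblage stage ----------------------------------------------
        if config.stages.get("assemblage", True):
            failed = "assemblage"
            seed = int(params["seed"])
            hm = community.habitat_matrix(records)
            hm, removed = community.filter_single_habitat_species(hm)
            writer.frame("habitat_matrix.csv", hm)
            if hm.shape[1] >= 4 and hm.shape[0] >= 2:
                dm = community.bray_curtis(hm.T)  # habitats as samples
                writer.frame("dissimilarity.csv", dm.to_frame())
                ord_res = community.nmds(
                    dm, k=2, n_starts=int(params.get("n_starts", 10)),
                    seed=seed)
                writer.frame("ordination.csv", ord_res.to_frame())
                writer.json("ordination.json", {
                    "stress": round(ord_res.stress, 6),
                    "n_starts": ord_res.n_starts,
                    "best_start": ord_res.best_start,
                    "converged": ord_res.converged, "seed": seed,
                })
                # MRPP per habitat-descriptor variable
                mrpp_out = {}
                descriptors = {
                    "site_type_group": [h.split("|")[0] for h in dm.labels],
                    "tree_class": [h.split("|")[1] if "|" in h else "special"
                                   for h in dm.labels],
                }
                testable = {k: v for k, v in descriptors.items()
                            if _testable_groups(v)}
                for var, glab in testable.items():
                    sub_dm, sub_groups = _drop_singleton_groups(dm, glab)
                    res = community.mrpp(
                        sub_dm, sub_groups,
                        B=int(params.get("permutations", 999)),
                        seed=seed, m_comparisons=len(testable))
                    mrpp_out[var] = {
                        "A": round(res.A, 4), "delta_obs": round(res.delta_obs, 6),
                        "expected_delta": round(res.expected_delta, 6),
                        "p_raw": round(res.p_raw, 6),
                        "p_adjusted": round(res.p_adjusted, 6),
                        "B": res.B, "exact": res.exact,
                    }
                writer.json("mrpp.json", mrpp_out)
                # habitat set overlaps over site-type groups
                lists: dict[str, set] = {}
                for h in hm.columns:
                    group = h.split("|")[0]
                    lists.setdefault(group, set()).update(
                        hm.index[hm[h] > 0])
                combos = [(g,) for g in sorted(lists)]
                overlap = community.overlap_counts(lists, combos)
                writer.json("overlaps.json", overlap.as_dict())
                logger.info("assemblage: habitats=%d species=%d stress=%.3f",
                            hm.shape[1], hm.shape[0], ord_res.stress)
            manifest["stages_run"].append("assemblage")
        failed = None
    finally:
        if failed is not None:
            manifest["failed_stage"] = failed
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _testable_groups(labels: Sequence[str]) -> bool:
    counts = pd.Series(labels).value_counts()
    return (counts >= 2).sum() >= 2


def _drop_singleton_groups(dm: "community.DissimilarityMatrix",
                           labels: Sequence[str]
                           ) -> tuple["community.DissimilarityMatrix", list[str]]:
    """Subset the dissimilarity matrix to samples whose group has at
    least two members (MRPP precondition)."""
    counts = pd.Series(labels).value_counts()
    keep = [i for i, g in enumerate(labels) if counts[g] >= 2]
    sub = community.DissimilarityMatrix(
        labels=[dm.labels[i] for i in keep],
        D=dm.D[np.ix_(keep, keep)])
    return sub, [labels[i] for i in keep]
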