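"""End-to-end orchestration: curate -> map -> diversity -> enumerate ->
energize -> capstone -> sample -> shift, from a single declarative config.

Every stage writes its table under the output directory; a versioned JSON
report collects counts, state-space ranges, ensemble summaries, and the
capstone list. All stochastic stages take their seed from the config, so a
rerun with the same config is byte-identical. Stage failures abort with the
stage name; a MANIFEST file records which outputs are complete.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import catalog as cat
from . import diversity as div
from . import energetics as en
from . import ensemble as ens
from . import state_space as ss
from . import synthetic as syn

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str = "archhist_run"
    seed: int = 0
    # input paths; any may be None when the synthetic generator is used
    fasta: str | None = None
    alignment: str | None = None
    abundance: str | None = None
    energy_table: str | None = None
    simulate: bool = False
    # curation
    min_len: int = cat.DEFAULT_MIN_LEN
    max_len: int = cat.DEFAULT_MAX_LEN
    max_gap_frac: float = cat.DEFAULT_MAX_GAP_FRAC
    reference_id: str | None = None
    # state space / energetics
    enumeration_mode: str = "ORDERED"
    backend: str = "surrogate"  # "surrogate" | "table"
    target_species: str | None = None
    reference_complex: str | None = None
    # diversity
    group_a: str = "multi"
    group_b: str = "single"
    # sampling
    n_draws: int = 100_000
    n_bins: int = 50
    pseudocount: float = 1.0
    conditions: tuple[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.conditions, list):
            cfg.conditions = tuple(cfg.conditions)
        return cfg

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise PipelineError("min_len > max_len")
        if self.enumeration_mode not in ("ORDERED", "CANONICAL"):
            raise PipelineError(f"bad enumeration_mode {self.enumeration_mode!r}")
        if self.backend not in ("surrogate", "table"):
            raise PipelineError(f"bad backend {self.backend!r}")
        if not self.simulate:
            if self.fasta is None or self.alignment is None:
                raise PipelineError(
                    "non-synthetic runs need fasta and alignment paths"
                )
            for label in ("fasta", "alignment", "abundance", "energy_table"):
                p = getattr(self, label)
                if p is not None and not Path(p).exists():
                    raise PipelineError(f"{label} path does not exist: {p}")
        if self.backend == "table" and not self.simulate and self.energy_table is None:
            raise PipelineError("table backend requires an energy_table path")


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
    }
    stage = "init"

    def _done(name: str, payload: Mapping[str, Any]) -> None:
        report["stages"][name] = dict(payload)
        manifest.append(name)

    try:
        # ------------------------------------------------------ inputs
        stage = "inputs"
        labeling: div.GroupLabeling | None = None
        abundance = None
        if config.simulate:
            spec = syn.SyntheticSpec(seed=config.seed)
            sim = syn.gen_catalog(spec)
            catalog, aligned, posmap = sim.catalog, sim.aligned, sim.posmap
            labeling = sim.labeling
            reference_id = sim.truth["reference_id"]
            cat.write_fasta(catalog, out / "catalog.fasta")
            cat.write_alignment(aligned, out / "alignment.fasta")
            _done("simulate", {"n_records": len(catalog),
                               "n_capstones_planted": len(sim.truth["capstone_ids"])})
        else:
            catalog = cat.read_fasta(config.fasta)
            aligned = cat.read_alignment(config.alignment)
            reference_id = config.reference_id or catalog.ids[0]
            if config.abundance:
                abundance = ens.read_abundance_tsv(config.abundance)
            groups = catalog.species_groups()
            labeling = div.GroupLabeling(
                {r.id: groups[r.species_id] for r in catalog}
            )
            _done("inputs", {"n_records": len(catalog)})

        # ------------------------------------------------------ curate
        stage = "curate"
        removed: list[cat.RemovalRecord] = []
        catalog, rem = cat.filter_by_length(catalog, config.min_len, config.max_len)
        removed += rem
        catalog, rem = cat.dedupe_identical(catalog, seed=config.seed)
        removed += rem
        aligned = cat.remove_gappy_columns(aligned, config.max_gap_frac)
        cat.write_removal_log(removed, out / "removal_log.tsv")
        _done("curate", {
            "n_kept": len(catalog), "n_removed": len(removed),
            "n_columns_kept": int(aligned.column_kept_mask.sum()),
        })

        # ------------------------------------------------------ map
        stage = "map"
        posmap = cat.build_position_map(aligned, reference_id)
        cat.write_position_map(posmap, out / "position_map.tsv")
        _done("map", {"reference_id": reference_id,
                      "n_positions": len(posmap.positions)})

        # ------------------------------------------------------ diversity
        stage = "diversity"
        if labeling is not None:
            profile = div.diversity_ratio_profile(
                aligned, posmap, labeling, config.group_a, config.group_b
            )
            profile.to_tsv(out / "diversity_profile.tsv")
            top = profile.ranked_positions()[:10]
            _done("diversity", {"group_a": config.group_a,
                                "group_b": config.group_b,
                                "top_positions": top})

        # ------------------------------------------------------ enumerate
        stage = "enumerate"
        counts = catalog.paralog_counts()
        target = config.target_species or max(counts, key=lambda s: counts[s])
        paralogs = [r.id for r in catalog if r.species_id == target]
        enumerated = ss.enumerate_tetramers(paralogs, mode="ORDERED")
        _done("enumerate", {"species": target, "n_paralogs": len(paralogs),
                            "n_complexes": len(enumerated),
                            "mode": config.enumeration_mode})

        # ------------------------------------------------------ energize
        stage = "energize"
        rows = {r.id: aligned.row(r.id) for r in catalog}
        if config.simulate:
            terms, _etruth = syn.gen_energy_table(
                spec, paralogs, capstone_ids=sim.truth["capstone_ids"],
                seed=config.seed,
            )
            en.write_additive_table(terms, out / "energy_table.tsv")
            backend: en.EnergyBackend = en.AdditiveTableBackend(
                terms, reference_id=paralogs[0]
            )
        elif config.backend == "table":
            backend = en.load_energy_table(config.energy_table)
        else:
            ref_key = config.reference_complex or "+".join([paralogs[0]] * 4)
            backend = en.SurrogateBackend(
                rows, posmap, ss.TetramerComplex.from_key(ref_key)
            )
        energies = {c.key: backend.energy(c) for c in enumerated}
        table = ss.complex_table(enumerated, energies)
        table.to_csv(out / "complexes.tsv", sep="\t", index=False)
        summary = ss.summarize_state_space(enumerated, energies)
        summary.to_csv(out / "state_space_summary.tsv", sep="\t", index=False)
        allrow = summary[summary.group == "ALL"].iloc[0]
        _done("energize", {
            "backend": backend.backend_tag,
            "bind_range": [float(allrow.bind_min), float(allrow.bind_max)],
            "tet_range": [float(allrow.tet_min), float(allrow.tet_max)],
        })

        # ------------------------------------------------------ capstone
        stage = "capstone"
        calls = [
            ss.capstone_call(r.id, aligned.row(r.id), posmap) for r in catalog
        ]
        with open(out / "capstones.tsv", "w") as fh:
            fh.write("monomer_id\tresidue49\tclass\tbasis\n")
            for c in calls:
                fh.write(f"{c.monomer_id}\t{c.residue49}\t{c.clazz}\t{c.basis}\n")
        capstones = [c.monomer_id for c in calls if c.clazz == "CAPSTONE"]
        _done("capstone", {"n_capstones": len(capstones),
                           "capstones": capstones[:50]})

        # ------------------------------------------------------ sample + shift
        stage = "sample"
        if config.simulate:
            stability = en.homotetramer_stability(backend, paralogs)
            abundance, _atruth = syn.gen_abundance(spec, stability,
                                                   seed=config.seed)
            ens.write_abundance_tsv(abundance, out / "abundance.tsv")
        if abundance is not None:
            conds = config.conditions or tuple(
                dict.fromkeys(abundance["condition"])
            )[:2]
            ensembles = []
            for i, cond in enumerate(conds):
                probs = ens.normalize_abundance(abundance, cond, paralogs)
                e = ens.sample_ensemble(probs, config.n_draws,
                                        seed=config.seed + i, condition=cond)
                ensembles.append(e)
            ens.ensemble_counts_tsv(ensembles, out / "ensemble_counts.tsv")
            _done("sample", {"conditions": list(conds),
                             "n_draws": config.n_draws,
                             "seeds": [e.seed for e in ensembles]})
            stage = "shift"
            if len(ensembles) == 2:
                grid = ens.density_shift(ensembles[0], ensembles[1], backend,
                                         config.n_bins, config.pseudocount)
                grid.to_tsv(out / "density_shift.tsv")
                _done("shift", grid.summary)
    except Exception as exc:
        (out / "MANIFEST").write_text(
            "\n".join(manifest + [f"INCOMPLETE: failed at stage {stage}"]) + "\n"
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "MANIFEST").write_text("\n".join(manifest + ["COMPLETE"]) + "\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report
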