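"""End-to-end orchestration: simulate -> genotype -> indices -> inference ->
randomization -> LD, driven by one YAML config and one master seed.

Every stage draws from a named substream of the master seed, so re-running
any stage in isolation reproduces its outputs, and identical (config, seed)
reproduce the whole run byte-for-byte (timestamps excluded by design: none
are written).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._seeds import child_seed
from .indices import INDEX_NAMES, aa_distance_matrix, compute_index
from .inference import ModelSpec, build_choice_table, lrt_parametric_bootstrap
from .io import (
    read_allele_fasta,
    read_events,
    read_genotypes,
    write_allele_fasta,
    write_events,
    write_genotypes,
)
from .linkage import taar_mhc_screen
from .randomization import mc_randomization_test
from .simulate import (
    PreferenceSpec,
    default_config,
    generate_catalogs,
    generate_population,
    simulate_choices,
)

__all__ = ["RunConfig", "run_full_analysis", "validate_inputs"]


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "mhcmate_run"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "indices", "randomize", "infer", "ld"]
    )
    population: dict = field(default_factory=dict)
    genes: list[str] | None = None
    preference: dict = field(
        default_factory=lambda: {"index_name": "MALDiv", "beta": 0.0, "target_gene": "MHC1"}
    )
    n_offspring: int = 133
    analysis_gene: str = "MHC1"
    analysis_indices: list[str] = field(default_factory=lambda: list(INDEX_NAMES))
    randomization_B: int = 10_000
    n_boot: int = 199
    ld_pairs: list[list[str]] | None = None
    ld_n_perm: int = 2_000

    _KNOWN_STAGES = ("simulate", "indices", "randomize", "infer", "ld")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for s in self.stages:
            if s not in self._KNOWN_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        for idx in self.analysis_indices:
            if idx not in INDEX_NAMES:
                raise ValueError(f"unknown index {idx!r}")
        pref_idx = self.preference.get("index_name", "MALDiv")
        if pref_idx not in INDEX_NAMES:
            raise ValueError(f"unknown preference index {pref_idx!r}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; intermediates are
    written to the run directory and the report returned (and written)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
        }
    }

    pop_cfg = default_config(**config.population)
    if config.genes:
        pop_cfg = pop_cfg.with_genes(*config.genes)
    catalogs = generate_catalogs(pop_cfg, child_seed(config.seed, "catalogs"))

    if "simulate" in config.stages:
        population = generate_population(
            pop_cfg, catalogs, child_seed(config.seed, "population")
        )
        pref = PreferenceSpec(**config.preference)
        D_pref = (
            aa_distance_matrix(catalogs[pref.target_gene])
            if pref.index_name in ("muAADis", "MAADiv")
            else None
        )
        events, offspring = simulate_choices(
            population, pref, config.n_offspring, child_seed(config.seed, "choices"), D=D_pref
        )
        genotypes = population.genotype_table()
        for gene_name, cat in sorted(catalogs.items()):
            write_allele_fasta(cat, out / f"catalog_{gene_name}.fasta")
        write_genotypes(genotypes, out / "genotypes.tsv")
        write_events(events, out / "events.tsv")
        report["simulate"] = {
            "n_individuals": len(population.individuals),
            "n_events": len(events),
            "n_offspring": len(offspring),
        }
    else:
        genotypes = read_genotypes(out / "genotypes.tsv")
        events = read_events(out / "events.tsv")

    gene = config.analysis_gene
    D = aa_distance_matrix(catalogs[gene]) if catalogs[gene][0].aa else None

    if "indices" in config.stages:
        rows = []
        for ev in events:
            mset = genotypes.get(ev.mother_id, gene)
            fset = genotypes.get(ev.father_id, gene)
            if mset is None or fset is None:
                continue
            row = {"offspring_id": ev.offspring_id}
            for idx in config.analysis_indices:
                iv = compute_index(idx, mset, fset, D)
                row[idx] = iv.value if iv.defined else ""
            rows.append(row)
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / f"indices_{gene}.tsv", sep="\t", index=False)
        report["indices"] = {"gene": gene, "n_couples": len(rows)}

    if "randomize" in config.stages:
        rnd = {}
        for idx in config.analysis_indices:
            res = mc_randomization_test(
                events, genotypes, gene, idx, D=D,
                B=config.randomization_B,
                seed=child_seed(config.seed, f"randomize:{idx}"),
            )
            rnd[idx] = {
                "observed_mean": res.observed_mean,
                "center": res.center,
                "p_two_tailed": res.p_two_tailed,
                "B": res.B,
                "n_couples": res.n_couples,
            }
        report["randomization"] = {"gene": gene, "results": rnd}

    if "infer" in config.stages:
        inf = {}
        for idx in config.analysis_indices:
            table, log = build_choice_table(events, genotypes, gene, idx, D=D)
            if log["events_out"] < 2:
                inf[idx] = {"skipped": "too few usable events", "log": log}
                continue
            lrt = lrt_parametric_bootstrap(
                table, ModelSpec(index=True), ModelSpec(index=False),
                n_boot=config.n_boot,
                seed=child_seed(config.seed, f"lrt:{idx}"),
            )
            inf[idx] = {
                "slope": lrt.full_fit.slope,
                "slope_se": lrt.full_fit.slope_se,
                "lrt_statistic": lrt.statistic,
                "p_value": lrt.p_value,
                "n_boot": lrt.n_boot,
                "n_rows": len(table),
                "n_chosen": int(table["CHOSEN"].sum()),
                "variances": lrt.full_fit.result.variances,
            }
        report["inference"] = {"gene": gene, "results": inf}

    if "ld" in config.stages:
        pairs = (
            [tuple(p) for p in config.ld_pairs]
            if config.ld_pairs
            else None
        )
        screen = taar_mhc_screen(
            genotypes,
            gene_pairs=pairs,
            n_perm=config.ld_n_perm,
            seed=child_seed(config.seed, "ld"),
        )
        screen.to_csv(out / "ld_screen.tsv", sep="\t", index=False)
        report["ld"] = screen.to_dict(orient="records")

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def validate_inputs(
    genotypes_path: str | Path | None = None,
    events_path: str | Path | None = None,
    fasta_paths: list[str | Path] | None = None,
) -> dict:
    """Cross-reference checks over the on-disk inputs; returns
    {"errors": [...], "warnings": [...]}. Errors are violations of the data
    contract; warnings mark optional pieces that are absent."""
    errors: list[str] = []
    warnings_: list[str] = []
    genotypes = None
    catalog_ids: dict[str, set[str]] = {}
    if fasta_paths:
        for p in fasta_paths:
            for a in read_allele_fasta(p):
                catalog_ids.setdefault(a.gene, set()).add(a.allele_id)
    if genotypes_path is not None:
        try:
            genotypes = read_genotypes(genotypes_path)
        except Exception as exc:  # malformed TSV
            errors.append(f"genotypes: unreadable ({exc})")
        if genotypes is not None and catalog_ids:
            for (ind, gene), alleles in genotypes.items():
                known = catalog_ids.get(gene)
                if known is None:
                    continue
                for a in alleles - known:
                    errors.append(f"genotypes: allele {a} of {ind}/{gene} missing from FASTA")
    if events_path is not None:
        try:
            events = read_events(events_path)
        except Exception as exc:
            errors.append(f"events: unreadable ({exc})")
            events = []
        seen = set()
        genes = genotypes.genes() if genotypes is not None else []
        for ev in events:
            if ev.offspring_id in seen:
                errors.append(f"events: duplicate offspring {ev.offspring_id}")
            seen.add(ev.offspring_id)
            for gene in genes:
                if genotypes.get(ev.father_id, gene) is None:
                    warnings_.append(
                        f"events: father {ev.father_id} not genotyped at {gene}"
                    )
    else:
        warnings_.append("events: not provided; inference stages will be skipped")
    return {"errors": errors, "warnings": warnings_}
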