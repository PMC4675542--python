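"""End-to-end orchestration: QC -> scan -> mine -> epistasis -> model -> transfer.

Mirrors the workflow of a two-stage candidate-gene study: Hardy-Weinberg and
LD screens, single-variant carriage scan, allelic-combination mining with
permutation adjustment and the minimality filter, SF+FLINT on every surviving
multi-element combination, a composite logistic model over the flagged
markers, and verbatim transfer of the trained model to a replication cohort.
All stage outputs are plain DataFrames; the report is regenerable
bit-identically from (data, config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import SignificanceGates, hwe_scan, ld_scan, single_variant_scan
from .combos import mine_combinations
from .epistasis import build_3way_table, flint_exact_test, sf_flint_decision, synergy_factor
from .io import CarriagePattern, GenotypeDataset, read_native
from .model import MarkerSet, fit_composite_logistic, apply_model, roc_auc


@dataclass
class PipelineConfig:
    max_order: int = 2
    permutations: int = 100
    hwe_threshold: float = 0.01
    hwe_policy: str = "flag"  # 'flag' | 'exclude'
    gates: SignificanceGates = field(default_factory=SignificanceGates)
    permutation_scope: str = "family"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gates = d.pop("gates", None)
        cfg = cls(**d)
        if gates:
            cfg.gates = SignificanceGates(**gates)
        return cfg


@dataclass
class RunReport:
    hwe: pd.DataFrame
    ld: pd.DataFrame
    single_variant: pd.DataFrame
    combinations: pd.DataFrame
    epistasis: pd.DataFrame
    model: dict | None
    thresholds: dict
    seed: int
    version: str
    warnings: list[str]

    def stage_tables(self) -> dict[str, pd.DataFrame]:
        return {
            "hwe": self.hwe,
            "ld": self.ld,
            "single_variant": self.single_variant,
            "combinations": self.combinations,
            "epistasis": self.epistasis,
        }

    def write(self, out_dir: str | Path, fmt: str = "tsv") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.stage_tables().items():
            if fmt == "tsv":
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
            else:
                (out / f"{name}.json").write_text(df.to_json(orient="records", indent=2))
        master = {
            "version": self.version,
            "seed": self.seed,
            "thresholds": self.thresholds,
            "warnings": self.warnings,
            "model": self.model,
            "stages": {k: f"{k}.{ 'tsv' if fmt == 'tsv' else 'json'}" for k in self.stage_tables()},
        }
        (out / "report.json").write_text(json.dumps(master, indent=2, sort_keys=True) + "\n")


def _records_frame(records, gates: SignificanceGates) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "pattern": r.pattern.label,
                "order": r.pattern.order,
                "n11": r.table.n11, "n10": r.table.n10,
                "n01": r.table.n01, "n00": r.table.n00,
                "freq_case": round(r.freq_case, 6),
                "freq_control": round(r.freq_control, 6),
                "OR": round(r.or_result.OR, 6),
                "ci_low": round(r.or_result.ci_low, 6),
                "ci_high": round(r.or_result.ci_high, 6),
                "p_f": r.p_f,
                "p_perm": r.p_perm if r.p_perm is not None else "",
                "minimal": bool(r.minimal) if r.minimal is not None else "",
                "significant": r.significant(gates),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    discovery: GenotypeDataset | str | Path,
    replication: GenotypeDataset | str | Path | None = None,
    config: PipelineConfig | None = None,
) -> RunReport:
    """Execute the full analysis and return the structured report."""
    cfg = config or PipelineConfig()
    if not isinstance(discovery, GenotypeDataset):
        with open(discovery) as fh:
            discovery = read_native(fh)
    if replication is not None and not isinstance(replication, GenotypeDataset):
        with open(replication) as fh:
            replication = read_native(fh)

    warns: list[str] = []

    # ---- stage 1: HWE screen (controls, then cases for reporting) ----
    hwe_rows = []
    violating: set[str] = set()
    for group in ("control", "case"):
        for lid, res in hwe_scan(discovery, group=group).items():
            ok = res.p > cfg.hwe_threshold
            hwe_rows.append(
                {"locus": lid, "group": group, "p": res.p, "method": res.method,
                 "monomorphic": res.monomorphic, "in_hwe": ok}
            )
            if not ok and group == "control":
                violating.add(lid)
    hwe_df = pd.DataFrame(hwe_rows)
    data = discovery
    if cfg.hwe_policy == "exclude" and violating:
        keep = [l.id for l in data.loci if l.id not in violating]
        warns.append(f"excluded HWE-violating loci: {sorted(violating)}")
        data = _subset_loci(data, keep)
    elif violating:
        warns.append(f"HWE-violating loci flagged (retained): {sorted(violating)}")

    # ---- stage 2: LD screen ----
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        ld = ld_scan(data)
    warns += [str(w.message) for w in wlist]
    ld_df = pd.DataFrame(
        [
            {"locusA": a, "locusB": b, "D": round(r.D, 6), "Dprime": round(r.Dprime, 6),
             "LOD": round(r.LOD, 6), "linkage_class": r.linkage_class}
            for (a, b), r in ld.items()
        ]
    )

    # ---- stage 3: single-variant scan ----
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        sv_records = single_variant_scan(data, gates=cfg.gates)
    warns += [str(w.message) for w in wlist]
    sv_df = _records_frame(sv_records, cfg.gates)

    # ---- stage 4: combination mining ----
    mined = mine_combinations(
        data, max_order=cfg.max_order, R=cfg.permutations,
        seed=cfg.seed, gates=cfg.gates, scope=cfg.permutation_scope,
    )
    combo_df = _records_frame(mined, cfg.gates)

    # ---- stage 5: SF+FLINT on surviving multi-element combinations ----
    surviving = [
        r for r in mined
        if r.pattern.order == 2 and r.minimal and r.significant(cfg.gates)
    ]
    epi_rows = []
    for rec in surviving:
        e1, e2 = rec.pattern.sorted_elements
        table = build_3way_table(data, e1, e2)
        sf = synergy_factor(table, alpha=cfg.gates.alpha)
        fl = flint_exact_test(table)
        verdict = sf_flint_decision(sf, fl, flint_alpha=cfg.gates.p_perm)
        epi_rows.append(
            {"factorA": e1.label, "factorB": e2.label,
             **{f"n{a}{b}{y}": int(table.n[a, b, y])
                for a in (0, 1) for b in (0, 1) for y in (0, 1)},
             "SF": round(sf.SF, 6), "sf_ci_low": round(sf.ci_low, 6),
             "sf_ci_high": round(sf.ci_high, 6), "p_flint": fl.p, "call": verdict.call}
        )
    epi_df = pd.DataFrame(epi_rows)

    # ---- stage 6: composite model + replication transfer ----
    flagged_single = [r for r in sv_records if r.significant(cfg.gates)]
    markers: list[tuple[str, CarriagePattern]] = []
    seen_patterns: set[CarriagePattern] = set()
    for r in flagged_single:
        if r.or_result.OR >= 1 and r.pattern not in seen_patterns:
            markers.append((r.pattern.label, r.pattern))
            seen_patterns.add(r.pattern)
    for r in surviving:
        if r.pattern not in seen_patterns:
            markers.append((r.pattern.label, r.pattern))
            seen_patterns.add(r.pattern)
    model_block = None
    if markers and data.n_case > 0 and data.n_control > 0:
        mset = MarkerSet(markers)
        try:
            model = fit_composite_logistic(data, mset, on_separation="ridge")
            model_block = json.loads(model.to_json())
            if replication is not None:
                scores = apply_model(model, replication, mset)
                roc = roc_auc(scores, replication.phenotype)
                model_block["replication_auc"] = roc.auc
        except ValueError as exc:
            warns.append(f"composite model skipped: {exc}")

    return RunReport(
        hwe=hwe_df,
        ld=ld_df,
        single_variant=sv_df,
        combinations=combo_df,
        epistasis=epi_df,
        model=model_block,
        thresholds={
            "p_f": cfg.gates.p_f, "p_perm": cfg.gates.p_perm,
            "alpha": cfg.gates.alpha, "hwe": cfg.hwe_threshold,
            "hwe_policy": cfg.hwe_policy, "max_order": cfg.max_order,
            "permutations": cfg.permutations,
        },
        seed=cfg.seed,
        version=__version__,
        warnings=warns,
    )


def _subset_loci(dataset: GenotypeDataset, keep: list[str]) -> GenotypeDataset:
    idx = [j for j, l in enumerate(dataset.loci) if l.id in keep]
    return GenotypeDataset(
        samples=list(dataset.samples),
        phenotype=dataset.phenotype.copy(),
        sex=dataset.sex.copy(),
        loci=[dataset.loci[j] for j in idx],
        genotypes=dataset.genotypes[:, idx].copy(),
    )
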