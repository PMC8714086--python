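"""Assemble every analysis stage into one study-style report directory.

``full_report`` runs, in dependency order and with the kinship matrix
computed once per analysis set: pedigree completeness, inbreeding /
relatedness / effective-size estimates, generation intervals, gene-origin
parameters, subpopulation structure and the AR-based mating groups — each
for the whole pedigree file (PF) and for the reference population (RP)
where the distinction matters.  Outputs are delimited tables, a Newick
tree, a JSON index of all aggregates and a plain-text log; the JSON index
is byte-identical across re-runs on the same input and seed.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import completeness as comp
from . import gene_origin as go
from . import intervals as iv
from . import kinship as kin
from . import mating as mate
from . import structure as struct
from .pedigree import Pedigree, PedigreeError

__all__ = ["StudyReport", "full_report"]


@dataclass
class StudyReport:
    completeness_profile: pd.DataFrame
    kinship_pf: kin.KinshipSummary
    kinship_rp: kin.KinshipSummary
    ne: kin.NeEstimates
    intervals_all: iv.IntervalTable
    intervals_repro: iv.IntervalTable
    gene_origin_pf: go.GeneOriginReport
    gene_origin_rp: go.GeneOriginReport
    structure: struct.StructureReport
    mating_groups: mate.MatingGroups
    pairs: mate.PairRecommendation
    index: dict
    warnings: list[str]


def _round(x, nd=6):
    if x is None:
        return None
    if isinstance(x, float):
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "inf"
        return round(x, nd)
    return x


def _agg(summary: kin.KinshipSummary, sexes: pd.Series) -> dict:
    per = summary.per_animal()
    by_sex = {}
    for s in ("male", "female"):
        sel = per[sexes.reindex(per.index) == s]
        by_sex[s] = {
            "n": int(len(sel)),
            "F_mean": _round(float(sel["F"].mean()) if len(sel) else float("nan")),
            "AR_mean": _round(float(sel["AR"].mean()) if len(sel) else float("nan")),
        }
    return {
        "n": int(len(per)),
        "F_mean": _round(float(per["F"].mean())),
        "AR_mean": _round(float(per["AR"].mean())),
        "dF_mean": _round(float(per["dF"].mean())),
        "t_mean": _round(float(per["t"].mean())),
        "by_sex": by_sex,
    }


def full_report(ped: Pedigree, out_dir, *, seed: int = 0, pci_depth: int = 5,
                profile_depth: int = 7, pca_components: int = 2,
                genedrop_replicates: int = 10_000) -> StudyReport:
    """Run all stages and write the report directory; returns the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    warnings: list[str] = []

    def stage(name):
        t0 = time.perf_counter()

        def done():
            log.append(f"{name}: {time.perf_counter() - t0:.2f}s")
        return done

    ref_ids = sorted(ped.reference_ids)
    if not ref_ids:
        warnings.append("no reference flag present; reference analyses use the whole pedigree")
        ref_ids = list(ped.real_ids)
    pf_ids = list(ped.real_ids)
    sexes = pd.Series({r.id: r.sex for r in ped.records if not r.is_phantom})

    try:
        done = stage("completeness")
        prof_pf = comp.completeness_profile(ped, pf_ids, max_depth=profile_depth)
        prof_rp = comp.completeness_profile(ped, ref_ids, max_depth=profile_depth)
        profile = prof_pf.rename(columns={"prop_known": "pedigree_file"})
        profile["reference_population"] = prof_rp["prop_known"]
        table = comp.completeness_table(ped, depth=pci_depth)
        done()

        done = stage("kinship")
        kin_pf = kin.kinship_summary(ped, pf_ids)
        kin_rp = kin.kinship_summary(ped, ref_ids)
        ne = kin.ne_estimates(ped, ref_ids)
        classes_pf = kin.inbreeding_classes(kin_pf.F, sexes)
        classes_rp = kin.inbreeding_classes(kin_rp.F, sexes)
        done()

        done = stage("intervals")
        ints_all = iv.generation_intervals(ped, "all_offspring")
        ints_rep = iv.generation_intervals(ped, "reproducers_only")
        done()

        done = stage("gene_origin")
        go_pf = go.gene_origin_report(ped, pf_ids, genedrop=True,
                                      replicates=genedrop_replicates, seed=seed)
        go_rp = go.gene_origin_report(ped, ref_ids, genedrop=True,
                                      replicates=genedrop_replicates, seed=seed + 1)
        done()

        done = stage("structure")
        strep = struct.structure_report(ped, None, ref_ids, k=pca_components)
        done()

        done = stage("mating")
        groups = mate.classify_by_ar(kin_rp.AR)
        pairs = mate.recommend_pairs(ped, list(groups.group1))
        done()
    except PedigreeError as err:
        raise PedigreeError(f"report stage failed: {err}") from err

    # ---- write data files
    profile.to_csv(out / "completeness_profile.tsv", sep="\t", index=False)
    table.to_csv(out / "completeness_per_animal.tsv", sep="\t", index_label="id")
    kin_pf.per_animal().to_csv(out / "kinship_pedigree_file.tsv", sep="\t", index_label="id")
    kin_rp.per_animal().to_csv(out / "kinship_reference.tsv", sep="\t", index_label="id")
    classes_pf.to_csv(out / "inbreeding_classes_pedigree_file.tsv", sep="\t", index_label="class")
    classes_rp.to_csv(out / "inbreeding_classes_reference.tsv", sep="\t", index_label="class")
    ints_all.table.to_csv(out / "generation_intervals_all.tsv", sep="\t")
    ints_rep.table.to_csv(out / "generation_intervals_reproducers.tsv", sep="\t")
    go_rp.q_founder.rename("q").to_csv(out / "founder_contributions_reference.tsv",
                                       sep="\t", index_label="founder")
    strep.coancestry_means.to_csv(out / "subpop_coancestry.tsv", sep="\t", index_label="group")
    strep.fst_pairwise.to_csv(out / "fst_pairwise.tsv", sep="\t", index_label="group")
    (out / "fst_dendrogram.nwk").write_text(strep.newick + "\n")
    strep.pca.coords.to_csv(out / "pca_coordinates.tsv", sep="\t", index_label="id")
    pd.DataFrame({
        "component": np.arange(1, len(strep.pca.explained) + 1),
        "variance_fraction": strep.pca.explained,
    }).to_csv(out / "pca_scree.tsv", sep="\t", index=False)
    strep.heatmap.to_csv(out / "relationship_heatmap.tsv", sep="\t", index_label="id")
    pairs.pairs.to_csv(out / "recommended_pairs.tsv", sep="\t", index=False)

    def go_dict(r: go.GeneOriginReport) -> dict:
        return {
            "n": r.n_ref, "f": r.f, "fe": _round(r.fe), "fa": _round(r.fa),
            "fg": _round(r.fg_coancestry), "fg_genedrop": _round(r.fg_genedrop),
            "n50": r.n50, "GD": _round(r.GD), "GDstar": _round(r.GDstar),
            "loss_total_pct": _round(100 * r.loss_total, 4),
            "loss_founder_pct": _round(100 * r.loss_founder, 4),
            "loss_drift_pct": _round(100 * r.loss_drift, 4),
        }

    index = {
        "n_animals": len(pf_ids),
        "n_reference": len(sorted(ped.reference_ids)) or len(ref_ids),
        "seed": seed,
        "completeness": {
            "profile_generation_1_pf": _round(float(profile["pedigree_file"].iloc[0])),
            "profile_generation_1_rp": _round(float(profile["reference_population"].iloc[0])),
            "max_gen_mean_pf": _round(float(table["max_gen"].mean())),
            "full_gen_mean_pf": _round(float(table["full_gen"].mean())),
            "equiv_gen_mean_pf": _round(float(table["equiv_gen"].mean())),
            "pci_mean_pf": _round(float(table["pci"].mean())),
        },
        "kinship": {
            "pedigree_file": _agg(kin_pf, sexes),
            "reference_population": _agg(kin_rp, sexes),
            "classes_pf": classes_pf.to_dict(),
            "classes_rp": classes_rp.to_dict(),
        },
        "ne": {k: _round(v) if isinstance(v, float) else v
               for k, v in ne.to_dict().items()},
        "generation_intervals": {
            "all_offspring": {
                p: {"n": int(ints_all.table.loc[p, "n"]),
                    "mean": _round(ints_all.table.loc[p, "mean"], 4),
                    "sd": _round(ints_all.table.loc[p, "sd"], 4)}
                for p in ints_all.table.index
            },
            "reproducers_only": {
                p: {"n": int(ints_rep.table.loc[p, "n"]),
                    "mean": _round(ints_rep.table.loc[p, "mean"], 4),
                    "sd": _round(ints_rep.table.loc[p, "sd"], 4)}
                for p in ints_rep.table.index
            },
        },
        "gene_origin": {
            "pedigree_file": go_dict(go_pf),
            "reference_population": go_dict(go_rp),
        },
        "structure": {
            "fst_estimator": strep.fst_estimator,
            "n_groups": len(strep.groups),
            "fst_mean": _round(float(np.nanmean(
                strep.fst_pairwise.to_numpy()[np.triu_indices(len(strep.groups), k=1)]))
                if len(strep.groups) > 1 else float("nan")),
            "pca_variance_first_two": _round(float(strep.pca.explained[:2].sum())),
        },
        "mating": {
            "ar_low": groups.low,
            "ar_high": groups.high,
            "group_sizes": [len(groups.group1), len(groups.group2), len(groups.group3)],
            "n_recommended_pairs": int(len(pairs)),
            "mean_predicted_F": _round(float(pairs.pairs["predicted_F"].mean())
                                       if len(pairs) else float("nan")),
        },
        "warnings": warnings,
        "exclusions": {
            "interval_pairs_missing_date": ints_all.n_missing_date,
            "interval_pairs_negative_age": ints_all.n_negative_age,
            "interval_pairs_unknown_sex": ints_all.n_unknown_sex,
            "ne_animals_used": ne.n_deltaF,
            "ne_pairs_used": ne.n_pairs,
        },
    }
    (out / "index.json").write_text(json.dumps(index, indent=2, sort_keys=True) + "\n")
    (out / "report.log").write_text("\n".join(log) + "\n")

    return StudyReport(
        completeness_profile=profile,
        kinship_pf=kin_pf, kinship_rp=kin_rp, ne=ne,
        intervals_all=ints_all, intervals_repro=ints_rep,
        gene_origin_pf=go_pf, gene_origin_rp=go_rp,
        structure=strep, mating_groups=groups, pairs=pairs,
        index=index, warnings=warnings,
    )
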