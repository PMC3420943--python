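"""Orchestrate the analysis stages into a reproducible run.

Stage order: synth -> allele calling -> annotation -> population
differentiation -> association.  Every stochastic stage derives its seed
from the master seed with a fixed offset; identical configurations yield
identical outputs.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import pandas as pd

from . import __version__
from .allelecall import call_alleles
from .annotate import classify_alleles, lof_enrichment, ng86_dnds, scan_orf
from .annotate.orf import LofAnnotation
from .assoc import apply_transform, fit_association, stepwise_aic, validate_transform_plan
from .io import (
    read_clone_fasta,
    write_allele_groups_tsv,
    write_alleles_fasta,
    write_table,
)
from .popgen import category_chisq, records_from_tables, resampled_fst
from .synth import LocusSpec, SimulationConfig, simulate_metapopulation

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Error in a named stage, wrapping the offending record context."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def build_sim_config(config: dict) -> SimulationConfig:
    synth = dict(config.get("synth", {}))
    loci = tuple(LocusSpec(**spec) for spec in synth.pop("loci"))
    regulation = {
        (entry["species"], entry["locus"]): float(entry["multiplier"])
        for entry in synth.pop("regulation", [])
    }
    return SimulationConfig(
        loci=loci,
        regulation=regulation,
        seed=int(config.get("seed", 0)),
        **synth,
    )


def validate_config(config: dict) -> None:
    """Fail fast on invalid thresholds or transform plans."""
    assoc = config.get("assoc", {})
    validate_transform_plan(
        assoc.get("response_kind", "amount_ug"),
        assoc.get("response_transform", "ln_shift"),
    )
    validate_transform_plan(
        "expression", assoc.get("predictor_transform", "sqrt")
    )
    ac = config.get("allelecall", {})
    if not 0 <= ac.get("min_support", 0.7) <= 1:
        raise ValueError("min_support outside [0,1]")
    if ac.get("max_within_distance", 0.03) < 0:
        raise ValueError("max_within_distance < 0")
    if ac.get("d_merge", 1) < 0:
        raise ValueError("d_merge < 0")
    if config.get("annotate", {}).get("detection_floor", 0.05) < 0:
        raise ValueError("detection_floor < 0")
    if config.get("popgen", {}).get("n_fst_reps", 100) < 1:
        raise ValueError("n_fst_reps < 1")


def _longest_intact_reference(alleles, stage: str):
    """Data-driven reference CDS: longest intact-ORF consensus, ties by id."""
    from .annotate.orf import validate_reference

    best = None
    for allele in sorted(alleles, key=lambda a: a.id):
        try:
            validate_reference(allele.consensus)
        except ValueError:
            continue
        length = len(allele.consensus.replace("-", ""))
        if best is None or length > len(best.consensus.replace("-", "")):
            best = allele
    if best is None:
        raise PipelineError(stage, "no intact-ORF reference allele found")
    return best


def run_pipeline(config: dict, outdir) -> dict:
    """Run all stages; returns the run report (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_config(config)
    seed = int(config.get("seed", 0))
    report: dict = {
        "version": __version__,
        "config": config,
        "seed": seed,
        "warnings": [],
        "stages": {},
    }

    # ------------------------------------------------------------ synth
    try:
        sim_config = build_sim_config(config)
        dataset, truth = simulate_metapopulation(sim_config)
        synth_dir = outdir / "synth"
        paths = dataset.write(synth_dir)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("synth", str(exc)) from exc
    report["stages"]["synth"] = {
        "files": paths,
        "n_individuals": len(truth.genotypes),
        "n_loci": len(sim_config.loci),
        "parametric_fst": truth.parametric_fst,
    }

    # ------------------------------------------------------ allele calling
    ac_conf = config.get("allelecall", {})
    called: dict[str, tuple] = {}
    group_of_true_allele: dict[str, dict[str, str]] = {}
    try:
        for li, spec in enumerate(sim_config.loci):
            reads = read_clone_fasta(synth_dir / f"clones_{spec.name}.fasta")
            alleles, tree, supports, groups = call_alleles(
                reads,
                d_merge=ac_conf.get("d_merge", 1),
                n_boot=ac_conf.get("n_boot", 1000),
                seed=seed * 1000 + li,
                min_support=ac_conf.get("min_support", 0.7),
                max_within_distance=ac_conf.get("max_within_distance", 0.03),
            )
            called[spec.name] = (alleles, tree, supports, groups)
            write_alleles_fasta(alleles, outdir / f"alleles_{spec.name}.fasta")
            write_allele_groups_tsv(
                alleles, groups, outdir / f"allele_groups_{spec.name}.tsv"
            )
            if tree is not None:
                (outdir / f"tree_{spec.name}.nwk").write_text(tree.to_newick() + "\n")
            # majority vote: true source allele (encoded in read ids) -> group
            label_of_allele = {
                aid: g.label for g in groups for aid in g.member_allele_ids
            }
            votes: dict[str, Counter] = {}
            for allele in alleles:
                for read_id in allele.member_read_ids:
                    true_id = read_id.split(".")[1]
                    votes.setdefault(true_id, Counter())[
                        label_of_allele[allele.id]
                    ] += 1
            group_of_true_allele[spec.name] = {
                true_id: counts.most_common(1)[0][0]
                for true_id, counts in votes.items()
            }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("allelecall", str(exc)) from exc
    report["stages"]["allelecall"] = {
        locus: {
            "n_alleles": len(called[locus][0]),
            "n_groups": len(called[locus][3]),
        }
        for locus in called
    }

    # remap synth expression onto called group labels
    expression = dataset.expression.copy()
    expression["allele_group"] = [
        group_of_true_allele[row.locus].get(row.allele_group, row.allele_group)
        for row in expression.itertuples()
    ]
    expression = (
        expression.groupby(
            ["individual", "species", "population", "locus", "allele_group"],
            as_index=False,
        )["normalized_intensity"]
        .sum()
        .sort_values(["individual", "locus", "allele_group"], kind="stable")
        .reset_index(drop=True)
    )
    write_table(expression, outdir / "expression_groups.tsv")

    # -------------------------------------------------------- annotation
    an_conf = config.get("annotate", {})
    floor = an_conf.get("detection_floor", 0.05)
    try:
        lof_rows, enrich_rows, dnds_rows, categories = [], [], [], []
        for spec in sim_config.loci:
            alleles, _tree, _supports, groups = called[spec.name]
            reference = _longest_intact_reference(alleles, "annotate")
            annotations: dict[str, LofAnnotation] = {}
            for allele in alleles:
                ann = scan_orf(allele.consensus, reference.consensus, allele.id)
                annotations[allele.id] = ann
                for event in ann.events:
                    lof_rows.append(
                        {
                            "locus": spec.name,
                            "allele_id": allele.id,
                            "kind": event.kind,
                            "position": event.position,
                        }
                    )
                if ann.is_functional_cds:
                    lof_rows.append(
                        {
                            "locus": spec.name,
                            "allele_id": allele.id,
                            "kind": "none",
                            "position": 0,
                        }
                    )
            counts = {
                g.label: (
                    sum(
                        not annotations[a].is_functional_cds
                        for a in g.member_allele_ids
                    ),
                    len(g.member_allele_ids),
                )
                for g in groups
            }
            for label, p in lof_enrichment(counts).items():
                bad, total = counts[label]
                enrich_rows.append(
                    {
                        "locus": spec.name,
                        "group_label": label,
                        "nonfunctional": bad,
                        "total": total,
                        "fisher_p": p,
                    }
                )
            expr_locus = expression[expression["locus"] == spec.name]
            categories.extend(
                classify_alleles(
                    groups, annotations, expr_locus, detection_floor=floor
                )
            )
            ordered = sorted(alleles, key=lambda a: a.id)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    res = ng86_dnds(a.consensus, b.consensus)
                    dnds_rows.append(
                        {
                            "locus": spec.name,
                            "allele_a": a.id,
                            "allele_b": b.id,
                            "dn": res.dn,
                            "ds": res.ds,
                            "ratio": res.ratio,
                            "flags": ";".join(res.flags),
                        }
                    )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("annotate", str(exc)) from exc
    write_table(pd.DataFrame(lof_rows), outdir / "lof_annotations.tsv")
    write_table(pd.DataFrame(enrich_rows), outdir / "lof_enrichment.tsv")
    write_table(pd.DataFrame(dnds_rows), outdir / "dnds_pairs.tsv")
    category_frame = pd.DataFrame(
        [
            {
                "locus": c.locus,
                "group_label": c.group_label,
                "species": c.species,
                "category": c.category,
            }
            for c in categories
        ]
    )
    write_table(category_frame, outdir / "allele_categories.tsv")
    report["stages"]["annotate"] = {
        "n_lof_events": sum(r["kind"] != "none" for r in lof_rows),
        "n_category_rows": len(category_frame),
    }

    # ----------------------------------------------------------- popgen
    pg_conf = config.get("popgen", {})
    n_reps = pg_conf.get("n_fst_reps", 100)
    groupings = pg_conf.get("groupings", ["species", "population"])
    try:
        records = records_from_tables(
            expression, dataset.phenotype, detection_floor=floor
        )
        fst_rows, rep_rows = [], []
        for spec in sim_config.loci:
            for grouping in groupings:
                est = resampled_fst(
                    records,
                    spec.name,
                    grouping=grouping,
                    n_reps=n_reps,
                    seed=seed,
                )
                fst_rows.append(
                    {
                        "locus": spec.name,
                        "grouping": grouping,
                        "mean": est.mean,
                        "se": est.se,
                        "mean_clamped": max(est.mean, 0.0),
                        "n_reps": est.n_reps,
                        "flags": ";".join(est.flags),
                    }
                )
                for rep, value in enumerate(est.replicates):
                    rep_rows.append(
                        {
                            "locus": spec.name,
                            "grouping": grouping,
                            "replicate": rep,
                            "theta": value,
                        }
                    )
        chisq_rows = []
        table = category_frame.pivot_table(
            index="species",
            columns="category",
            values="group_label",
            aggfunc="count",
            fill_value=0,
        )
        if table.shape[0] >= 2 and table.shape[1] >= 2:
            result = category_chisq(table, seed=seed)
            chisq_rows.append(
                {
                    "test": "species_x_category",
                    "chi2": result.chi2,
                    "df": result.df,
                    "p": result.p,
                    "warnings": ";".join(result.warnings),
                }
            )
            report["warnings"].extend(result.warnings)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("popgen", str(exc)) from exc
    write_table(pd.DataFrame(fst_rows), outdir / "fst.tsv")
    write_table(pd.DataFrame(rep_rows), outdir / "fst_replicates.tsv")
    write_table(pd.DataFrame(chisq_rows), outdir / "category_chisq.tsv")
    report["stages"]["popgen"] = {"fst": fst_rows, "chisq": chisq_rows}

    # ------------------------------------------------------------ assoc
    as_conf = config.get("assoc", {})
    response_transform = as_conf.get("response_transform", "ln_shift")
    predictor_transform = as_conf.get("predictor_transform", "sqrt")
    try:
        per_locus = (
            expression.groupby(["individual", "locus"], as_index=False)[
                "normalized_intensity"
            ]
            .sum()
            .pivot(index="individual", columns="locus", values="normalized_intensity")
            .fillna(0.0)
        )
        pheno = dataset.phenotype
        causal_amount = (
            pheno[pheno["compound"] == sim_config.causal_compound]
            .set_index("individual")["amount_ug"]
            .reindex(per_locus.index)
        )
        population = (
            expression.drop_duplicates("individual")
            .set_index("individual")["population"]
            .reindex(per_locus.index)
        )
        response = apply_transform(
            causal_amount.to_numpy(),
            response_transform,
            name=sim_config.causal_compound,
        )
        predictors = [
            apply_transform(
                per_locus[locus].to_numpy(),
                predictor_transform,
                name=f"expr_{locus}",
            )
            for locus in sim_config.locus_names
        ]
        fits = [
            fit_association(response, predictors),
            fit_association(response, predictors, population=population.to_numpy()),
            stepwise_aic(response, predictors),
        ]
        assoc_rows = []
        for fit, kind in zip(fits, ["fixed_only", "random_intercept_population", "stepwise_final"]):
            for term in ("const",) + fit.terms:
                assoc_rows.append(
                    {
                        "response": fit.response,
                        "model": kind,
                        "term": term,
                        "estimate": fit.estimates[term],
                        "p": fit.pvalues[term],
                        "adj_r2": fit.adj_r2,
                        "aic": fit.aic,
                        "n": fit.n,
                    }
                )
        step_log = json.dumps(
            fits[2].metadata.get("elimination_path", []), indent=1
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("assoc", str(exc)) from exc
    write_table(pd.DataFrame(assoc_rows), outdir / "associations.tsv")
    (outdir / "stepwise_log.txt").write_text(step_log + "\n")
    report["stages"]["assoc"] = {
        "final_terms": list(fits[2].terms),
        "final_aic": fits[2].aic,
    }

    (outdir / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str)
    )
    return report
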