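"""End-to-end analysis pipeline and report stage.

Order of stages: validate inputs -> build similarity matrices -> per-site
diversity profiles (naive, taxonomic, four functional constraints; orders
q = 0, 1, 2) -> redundancy ratios -> permutation null model with SES and the
habitat-level zero-mean test -> habitat-comparison mixed models -> habitat
summaries and a human-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import similarity as sim
from .diversity import relative_abundance, similarity_diversity, redundancy
from .io import (
    AbundanceTable,
    ValidationError,
    check_species_consistency,
    read_abundance,
    read_taxonomy,
    read_traits,
)
from .mixedmodels import fit_diversity_model
from .nullmodel import (
    habitat_ses_test,
    null_model_test,
    ses_results_frame,
    shuffle_trait_rows,
)

logger = logging.getLogger(__name__)

FUNCTIONAL_CONSTRAINTS = (
    "host_plant",
    "larval_specialism",
    "overwintering_stage",
    "wingspan",
)


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    abundance_path: str | Path | None = None
    traits_path: str | Path | None = None
    taxonomy_path: str | Path | None = None
    constraints: tuple[str, ...] = sim.CONSTRAINTS
    q_values: tuple[float, ...] = (0.0, 1.0, 2.0)
    ses_q: float = 0.0
    ses_constraints: tuple[str, ...] = FUNCTIONAL_CONSTRAINTS
    n_perm: int = 999
    seed: int = 0
    random_structure: str = "pair"
    permutation_scheme: str = "abundance"
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if any(q < 0 for q in self.q_values) or self.ses_q < 0:
            raise ValidationError("orders q must be >= 0")
        unknown = set(self.constraints) - set(sim.CONSTRAINTS)
        if unknown:
            raise ValidationError(f"unknown constraints: {sorted(unknown)}")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.permutation_scheme not in ("abundance", "traits"):
            raise ValidationError(
                f"unknown permutation scheme {self.permutation_scheme!r}"
            )
        for path in (self.abundance_path, self.traits_path, self.taxonomy_path):
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input file not found: {path}")


@dataclass
class PipelineResult:
    diversity: pd.DataFrame
    redundancy: pd.DataFrame
    ses: pd.DataFrame
    habitat_ses: pd.DataFrame
    models: pd.DataFrame
    habitat_summary: pd.DataFrame
    report: str = ""
    provenance: dict = field(default_factory=dict)


def build_similarities(
    abundance: AbundanceTable,
    traits: pd.DataFrame | None,
    taxonomy: pd.DataFrame | None,
    constraints,
) -> dict[str, sim.SimilarityMatrix]:
    """One full-pool similarity matrix per requested constraint."""
    needs_traits = [c for c in constraints if c in FUNCTIONAL_CONSTRAINTS]
    if needs_traits and traits is None:
        raise ValidationError(
            f"constraints {needs_traits} require a trait table"
        )
    if "taxonomic" in constraints and taxonomy is None:
        raise ValidationError("taxonomic constraint requires a taxonomy table")
    check_species_consistency(
        abundance,
        traits if needs_traits else None,
        taxonomy if "taxonomic" in constraints else None,
    )
    species = abundance.species_ids
    out = {}
    for c in constraints:
        out[c] = sim.constraint_similarity(c, species, traits=traits, taxonomy=taxonomy)
    return out


def site_diversity_table(
    abundance: AbundanceTable,
    similarities: dict[str, sim.SimilarityMatrix],
    q_values,
) -> pd.DataFrame:
    """Long-format per-site effective numbers: site_id, constraint, q, value.

    Each site is treated as its own subcommunity: zero-count species are
    dropped and Z is subset to the species present.
    """
    rows = []
    for site in abundance.site_ids:
        counts = abundance.site_counts(site)
        p = relative_abundance(counts.to_numpy(), abundance.species_ids)
        for name, Z in similarities.items():
            z_sub = Z.subset(p.species_ids)
            for q in q_values:
                rows.append(
                    {
                        "site_id": site,
                        "habitat": abundance.habitat_of(site),
                        "constraint": name,
                        "q": float(q),
                        "effective_number": similarity_diversity(p, z_sub, q),
                    }
                )
    return pd.DataFrame(rows)


def redundancy_table(
    abundance: AbundanceTable, similarities: dict[str, sim.SimilarityMatrix]
) -> pd.DataFrame:
    """Per-site redundancy (naive / constrained richness) per constraint."""
    rows = []
    for site in abundance.site_ids:
        counts = abundance.site_counts(site).to_numpy()
        for name, Z in similarities.items():
            if name == "naive":
                continue
            r = redundancy(
                counts, Z, abundance.species_ids, site_id=site, constraint=name
            )
            rows.append(
                {
                    "site_id": site,
                    "habitat": abundance.habitat_of(site),
                    "constraint": name,
                    "naive_richness": r.naive_richness,
                    "constrained_richness": r.constrained_richness,
                    "redundancy": r.redundancy,
                }
            )
    return pd.DataFrame(rows)


def summarize_habitats(values, habitats) -> pd.DataFrame:
    """Per-habitat mean and sd plus percent-of-broadleaf contrasts.

    Percent ratio = plantation mean / broadleaf mean x 100; percent deficit
    = (broadleaf - plantation) / broadleaf x 100.  A habitat with a single
    site gets a missing sd.
    """
    df = pd.DataFrame({"value": list(values), "habitat": list(habitats)})
    if df.empty or df.groupby("habitat").size().min() < 1:
        raise ValidationError("each habitat needs at least one site")
    agg = df.groupby("habitat")["value"].agg(["mean", "std", "count"])
    out = agg.rename(columns={"std": "sd", "count": "n_sites"}).reset_index()
    if {"broadleaf", "plantation"} <= set(out["habitat"]):
        mb = float(agg.loc["broadleaf", "mean"])
        mp = float(agg.loc["plantation", "mean"])
        if mb != 0:
            out["pct_of_broadleaf"] = np.where(
                out["habitat"] == "plantation", mp / mb * 100.0, 100.0
            )
            out["pct_deficit"] = np.where(
                out["habitat"] == "plantation", (mb - mp) / mb * 100.0, 0.0
            )
    return out


def fit_models(
    diversity: pd.DataFrame,
    redundancy_df: pd.DataFrame,
    abundance: AbundanceTable,
    random_structure: str = "pair",
) -> pd.DataFrame:
    """Mixed-model habitat comparison per constraint and order.

    Naive richness (q = 0) uses the Poisson family on the log link; all
    other diversity responses and the redundancy ratios are Gaussian.
    """
    meta = abundance.meta
    rows = []

    def _fit(values, sites, family, label):
        m = meta.loc[sites]
        fit = fit_diversity_model(
            values, m["habitat"], m["pair_id"], m["year"], m["month"],
            family=family, response=label, random_structure=random_structure,
        )
        rows.append(fit.summary_row())

    for (constraint, q), grp in diversity.groupby(["constraint", "q"], sort=False):
        family = "poisson" if (constraint == "naive" and q == 0) else "gaussian"
        values = grp["effective_number"].to_numpy()
        if family == "poisson":
            values = np.round(values).astype(int)
        _fit(values, grp["site_id"].tolist(), family, f"{constraint} q={q:g}")

    if redundancy_df.empty:
        return pd.DataFrame(rows)
    for constraint, grp in redundancy_df.groupby("constraint", sort=False):
        _fit(
            grp["redundancy"].to_numpy(), grp["site_id"].tolist(),
            "gaussian", f"redundancy {constraint}",
        )
    return pd.DataFrame(rows)


def run_null_models(
    abundance: AbundanceTable,
    similarities: dict[str, sim.SimilarityMatrix],
    constraints,
    q: float,
    n_perm: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    habitats = dict(zip(abundance.site_ids, abundance.meta["habitat"].astype(str)))
    ses_frames, habitat_rows = [], []
    constraints = list(constraints)
    if not constraints:
        return pd.DataFrame(), pd.DataFrame()
    children = np.random.SeedSequence(seed).spawn(len(constraints))
    for child, constraint in zip(children, constraints):
        results = null_model_test(
            abundance, similarities[constraint], q=q, n_perm=n_perm,
            seed=child, constraint=constraint, on_degenerate="skip",
        )
        if not results:
            continue
        ses_frames.append(ses_results_frame(results, habitats))
        counts_per_habitat = pd.Series(
            [habitats[r.site_id] for r in results]
        ).value_counts()
        if counts_per_habitat.empty or counts_per_habitat.min() < 2:
            continue
        for test in habitat_ses_test(results, habitats):
            habitat_rows.append(
                {
                    "habitat": test.habitat,
                    "constraint": test.constraint,
                    "q": test.q,
                    "mean_ses": test.mean_ses,
                    "se_ses": test.se_ses,
                    "p_value": test.p_value,
                    "n_sites": test.n_sites,
                }
            )
    if not ses_frames:
        return pd.DataFrame(), pd.DataFrame(habitat_rows)
    return pd.concat(ses_frames, ignore_index=True), pd.DataFrame(habitat_rows)


def habitat_summary_table(diversity: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (constraint, q), grp in diversity.groupby(["constraint", "q"], sort=False):
        summ = summarize_habitats(grp["effective_number"], grp["habitat"])
        summ.insert(0, "q", float(q))
        summ.insert(0, "constraint", constraint)
        rows.append(summ)
    return pd.concat(rows, ignore_index=True)


def render_report(result: "PipelineResult", n_perm: int) -> str:
    """Human-readable summary of habitat means, models and SES tests."""
    lines = ["Lepidopteran community diversity report", "=" * 40, ""]
    lines.append("Per-habitat effective numbers (mean +/- sd):")
    for (constraint, q), grp in result.habitat_summary.groupby(
        ["constraint", "q"], sort=False
    ):
        parts = []
        for _, r in grp.iterrows():
            sd = f"{r['sd']:.1f}" if np.isfinite(r["sd"]) else "NA"
            parts.append(f"{r['habitat']}: {r['mean']:.1f} +/- {sd}")
        line = f"  {constraint} (q={q:g}): " + "; ".join(parts)
        plant = grp[grp["habitat"] == "plantation"]
        if "pct_of_broadleaf" in grp.columns and len(plant):
            line += (
                f" | plantation = {plant['pct_of_broadleaf'].iloc[0]:.1f}% of"
                f" broadleaf (deficit {plant['pct_deficit'].iloc[0]:.1f}%)"
            )
        lines.append(line)
    lines.append("")
    lines.append("Habitat-comparison mixed models (broadleaf = reference):")
    for _, r in result.models.iterrows():
        star = " *" if r["significant"] else ""
        lines.append(
            f"  {r['response']:<28s} [{r['family']}] intercept "
            f"{r['intercept']:.2f} +/- {r['intercept_se']:.2f}, plantation "
            f"{r['plantation']:.2f} +/- {r['plantation_se']:.2f}{star}, "
            f"R2m {r['marginal_r2']:.2f}, R2c {r['conditional_r2']:.2f}"
        )
    lines.append("")
    lines.append(f"Null-model SES per habitat ({n_perm} permutations):")
    for _, r in result.habitat_ses.iterrows():
        lines.append(
            f"  {r['constraint']:<20s} {r['habitat']:<10s} SES "
            f"{r['mean_ses']:+.2f} +/- {r['se_ses']:.2f}, p = {r['p_value']:.2f}"
        )
    lines.append("")
    lines.append(
        "SES < 0: environmental filtering; SES > 0: niche complementarity."
    )
    return "\n".join(lines) + "\n"


def analyze_study(
    abundance: AbundanceTable,
    traits: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory tables."""
    config = config or PipelineConfig()
    config.validate()
    t0 = time.time()
    if config.permutation_scheme == "traits" and traits is not None:
        traits = shuffle_trait_rows(traits, np.random.SeedSequence(config.seed).spawn(3)[2])
    similarities = build_similarities(abundance, traits, taxonomy, config.constraints)
    _log_stage("similarity", abundance, config.seed, t0)
    diversity = site_diversity_table(abundance, similarities, config.q_values)
    _log_stage("diversity", abundance, config.seed, t0)
    red = redundancy_table(abundance, similarities)
    ses_constraints = [c for c in config.ses_constraints if c in similarities]
    ses_df, habitat_ses_df = run_null_models(
        abundance, similarities, ses_constraints, config.ses_q,
        config.n_perm, config.seed,
    )
    _log_stage("nullmodel", abundance, config.seed, t0)
    models = fit_models(diversity, red, abundance, config.random_structure)
    _log_stage("models", abundance, config.seed, t0)
    summary = habitat_summary_table(diversity)
    result = PipelineResult(
        diversity=diversity,
        redundancy=red,
        ses=ses_df,
        habitat_ses=habitat_ses_df,
        models=models,
        habitat_summary=summary,
        provenance={
            "seed": config.seed,
            "n_perm": config.n_perm,
            "q_values": list(config.q_values),
            "constraints": list(config.constraints),
            "random_structure": config.random_structure,
            "permutation_scheme": config.permutation_scheme,
            "abundance_sha1": _table_hash(abundance),
        },
    )
    result.report = render_report(result, config.n_perm)
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-facing wrapper: read the three CSVs, analyze, write artifacts."""
    config.validate()
    if config.abundance_path is None:
        raise ValidationError("abundance_path is required")
    abundance = read_abundance(config.abundance_path)
    traits = read_traits(config.traits_path) if config.traits_path else None
    taxonomy = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    result = analyze_study(abundance, traits, taxonomy, config)
    if config.out_dir is not None:
        write_artifacts(result, config.out_dir)
    return result


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.diversity.to_csv(out / "diversity.csv", index=False)
    result.redundancy.to_csv(out / "redundancy.csv", index=False)
    result.ses.to_csv(out / "ses.csv", index=False)
    result.habitat_ses.to_csv(out / "habitat_ses.csv", index=False)
    result.models.to_csv(out / "models.csv", index=False)
    result.habitat_summary.to_csv(out / "habitat_summary.csv", index=False)
    (out / "report.txt").write_text(result.report)
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))


def _table_hash(abundance: AbundanceTable) -> str:
    payload = abundance.to_frame().to_csv().encode()
    return hashlib.sha1(payload).hexdigest()


def _log_stage(stage: str, abundance: AbundanceTable, seed, t0: float) -> None:
    logger.info(
        "stage=%s sites=%d species=%d seed=%s elapsed=%.2fs",
        stage, abundance.n_sites, len(abundance.species_ids), seed,
        time.time() - t0,
    )
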