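"""End-to-end identification workflow and structured reporting.

One call runs the full chain on FASTA inputs: fragment-to-reference
mapping, per-site variability tabulation, population aggregation analysis
with query assignment, similarity ranking against the species database,
and the NJ/bootstrap tree check.  Every stage's artifacts are written
under the output directory and summarised in a single JSON report whose
bytes depend only on the inputs, the configuration and the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .blastlike import ScoringParams, hits_to_tsv, rank_database, tie_group_summary
from .io import LabeledAlignment, read_fasta
from .paa import (
    SITE_WISE,
    assign_query,
    diagnostic_combinations,
    species_profiles,
)
from .refmap import FragmentMapping, map_fragment
from .treecheck import (
    BOOTSTRAP_PCT,
    bootstrap_support,
    classify_support,
    split_support,
)
from .variability import (
    between_species_differences,
    tabulate,
    variable_positions,
    within_species_polymorphic,
)

log = logging.getLogger("barcodiag")


@dataclass
class RunConfig:
    """Configuration for a full identification run."""

    query_fasta: str
    reference_fasta: str
    database_fasta: str
    output_dir: str = "barcodiag_out"
    min_identity: float = 0.8
    reward: int = 1
    penalty: int = -2
    lam: float = 1.28
    K: float = 0.46
    kmax: int = 4
    assignment_mode: str = SITE_WISE
    bootstrap_replicates: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a plain-text ``key = value`` configuration file."""
        values: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(values) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {name: _coerce(name, values[name]) for name in values}
        missing = {"query_fasta", "reference_fasta", "database_fasta"} - set(kwargs)
        if missing:
            raise ValueError(f"config missing required keys: {sorted(missing)}")
        return cls(**kwargs)

    def scoring_params(self) -> ScoringParams:
        return ScoringParams(
            reward=self.reward, penalty=self.penalty, lam=self.lam, K=self.K
        )


_FIELD_TYPES = {
    "min_identity": float,
    "lam": float,
    "K": float,
    "reward": int,
    "penalty": int,
    "kmax": int,
    "bootstrap_replicates": int,
    "seed": int,
}


def _coerce(name: str, value):
    if isinstance(value, str):
        return _FIELD_TYPES.get(name, str)(value)
    return value


def run_identification(config: RunConfig) -> dict:
    """Execute the full pipeline; return (and write) the structured report.

    Stage failures do not abort the run: each failed or inapplicable stage
    is recorded with a skip reason and the partial report is still written.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.scoring_params()

    query_file = read_fasta(config.query_fasta)
    reference_aln = read_fasta(config.reference_fasta)
    database_file = read_fasta(config.database_fasta)
    if len(reference_aln) == 0:
        raise ValueError("reference FASTA is empty")
    # QUERY-labeled records are the queries; a file of nothing but
    # unlabeled sequences is taken to be all queries
    queries = LabeledAlignment(query_file.queries or list(query_file))
    if len(queries) == 0:
        raise ValueError("query FASTA is empty")
    # similarity and tree stages run against species records only
    database = LabeledAlignment([r for r in database_file if not r.is_query])
    reference = reference_aln[0]

    report: dict = {
        "provenance": {
            "tool": "barcodiag",
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
        },
        "stages": {},
    }

    # --- stage 1: fragment-to-reference mapping -------------------------
    mapping: FragmentMapping | None = None
    try:
        mapping = map_fragment(
            queries[0].sequence,
            reference.sequence,
            min_identity=config.min_identity,
            reference_id=reference.id,
        )
        if not mapping.mapped:
            raise ValueError(
                f"best identity {mapping.identity:.3f} below threshold "
                f"{config.min_identity}"
            )
        (outdir / "mapping.json").write_text(mapping.to_json() + "\n")
        (outdir / "mapping.tsv").write_text(
            "reference_id\tstart\tend\tstrand\tidentity\n" + mapping.to_tsv_row() + "\n"
        )
        report["stages"]["mapping"] = json.loads(mapping.to_json())
    except Exception as exc:  # noqa: BLE001 - per-stage fault isolation
        report["stages"]["mapping"] = {"skipped": True, "reason": str(exc)}
        log.warning("mapping stage failed: %s", exc)

    # --- stage 2: variability table -------------------------------------
    table = None
    combined = LabeledAlignment(list(database) + list(queries))
    species = database.species_labels
    if mapping is not None and mapping.mapped:
        try:
            table = tabulate(combined, mapping)
            var_pos = variable_positions(table)
            entry = {
                "variable_positions": var_pos,
                "sample_sizes": table.sample_sizes,
                "within_species_polymorphic": {
                    sp: within_species_polymorphic(table, sp) for sp in species
                },
            }
            if len(species) >= 2:
                entry["between_species_differences"] = between_species_differences(
                    table, species[0], species[1]
                )
            (outdir / "variability.tsv").write_text(
                table.to_frame(var_pos).to_csv(sep="\t") if var_pos else ""
            )
            (outdir / "variability.json").write_text(table.to_json(var_pos) + "\n")
            report["stages"]["variability"] = entry
        except Exception as exc:  # noqa: BLE001
            report["stages"]["variability"] = {"skipped": True, "reason": str(exc)}
            log.warning("variability stage failed: %s", exc)
    else:
        report["stages"]["variability"] = {
            "skipped": True,
            "reason": "no fragment mapping",
        }

    # --- stage 3: population aggregation analysis -----------------------
    if table is not None and len(species) >= 2:
        try:
            profiles = species_profiles(combined, mapping)
            diag = diagnostic_combinations(
                profiles, species[0], species[1], kmax=config.kmax
            )
            verdicts = [
                assign_query(q, profiles, mapping, mode=config.assignment_mode)
                for q in queries
            ]
            (outdir / "diagnostics.json").write_text(diag.to_json() + "\n")
            verdict_rows = ["query_id\tmode\tcompatible_species\tstatus"]
            for v in verdicts:
                verdict_rows.append(
                    f"{v.query_id}\t{v.mode}\t"
                    f"{','.join(sorted(v.compatible_species))}\t{v.status}"
                )
            (outdir / "verdicts.tsv").write_text("\n".join(verdict_rows) + "\n")
            report["stages"]["paa"] = {
                "any_diagnostic": diag.any_diagnostic,
                "single_site_diagnostics": diag.single_site_diagnostics,
                "n_combination_diagnostics": {
                    str(k): len(v) for k, v in diag.combination_diagnostics.items()
                },
                "verdicts": [
                    {
                        "query_id": v.query_id,
                        "compatible_species": sorted(v.compatible_species),
                        "status": v.status,
                        "mode": v.mode,
                    }
                    for v in verdicts
                ],
            }
        except Exception as exc:  # noqa: BLE001
            report["stages"]["paa"] = {"skipped": True, "reason": str(exc)}
            log.warning("PAA stage failed: %s", exc)
    else:
        report["stages"]["paa"] = {
            "skipped": True,
            "reason": "needs a variability table and at least two species",
        }

    # --- stage 4: similarity ranking ------------------------------------
    try:
        hits = rank_database(queries[0].sequence, database, params)
        (outdir / "hits.tsv").write_text(hits_to_tsv(hits))
        report["stages"]["similarity"] = {
            "top_displayed_bits": hits[0].displayed_bits,
            "tie_groups": tie_group_summary(hits),
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"]["similarity"] = {"skipped": True, "reason": str(exc)}
        log.warning("similarity stage failed: %s", exc)

    # --- stage 5: tree check --------------------------------------------
    species_only = database
    if len(species_only) >= 3 and len(species) >= 2:
        try:
            tree = bootstrap_support(
                species_only,
                n_replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            (outdir / "tree.nwk").write_text(tree.newick + "\n")
            per_species = {}
            for sp in species:
                ids = frozenset(r.id for r in species_only if r.species == sp)
                sup = split_support(tree, ids)
                per_species[sp] = {
                    "monophyly_split_in_tree": sup is not None,
                    "bootstrap_pct": sup,
                    "category": classify_support(sup, BOOTSTRAP_PCT)
                    if sup is not None
                    else "absent",
                }
            report["stages"]["tree_check"] = {
                "n_replicates": config.bootstrap_replicates,
                "species_monophyly": per_species,
            }
        except Exception as exc:  # noqa: BLE001
            report["stages"]["tree_check"] = {"skipped": True, "reason": str(exc)}
            log.warning("tree stage failed: %s", exc)
    else:
        report["stages"]["tree_check"] = {
            "skipped": True,
            "reason": "needs >= 3 database sequences and >= 2 species",
        }

    report_text = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_text + "\n")
    (outdir / "summary.txt").write_text(_summarise(report) + "\n")
    return report


def _summarise(report: dict) -> str:
    """Human-readable one-screen summary assembled from stage artifacts."""
    lines = [f"barcodiag v{report['provenance']['version']} identification summary"]
    stages = report["stages"]
    m = stages.get("mapping", {})
    if m.get("skipped"):
        lines.append(f"mapping: SKIPPED ({m['reason']})")
    else:
        lines.append(
            f"mapping: {m['reference_id']}:{m['ref_start']}-{m['ref_end']} "
            f"({m['strand']}, identity {m['identity']:.3f})"
        )
    v = stages.get("variability", {})
    if v.get("skipped"):
        lines.append(f"variability: SKIPPED ({v['reason']})")
    else:
        lines.append(f"variability: variable positions {v['variable_positions']}")
    p = stages.get("paa", {})
    if p.get("skipped"):
        lines.append(f"paa: SKIPPED ({p['reason']})")
    else:
        lines.append(f"paa: any diagnostic character/combination: {p['any_diagnostic']}")
        for verdict in p["verdicts"]:
            lines.append(
                f"  {verdict['query_id']}: {verdict['status']} "
                f"{{{', '.join(verdict['compatible_species'])}}}"
            )
    s = stages.get("similarity", {})
    if s.get("skipped"):
        lines.append(f"similarity: SKIPPED ({s['reason']})")
    else:
        tiers = ", ".join(
            f"group {g['tie_group']}: {g['size']} @ {g['displayed_bits']} bits"
            for g in s["tie_groups"][:3]
        )
        lines.append(f"similarity: {tiers}")
    t = stages.get("tree_check", {})
    if t.get("skipped"):
        lines.append(f"tree: SKIPPED ({t['reason']})")
    else:
        for sp, info in t["species_monophyly"].items():
            lines.append(
                f"tree: {sp} monophyly "
                + (
                    f"{info['bootstrap_pct']:.0f}% ({info['category']})"
                    if info["monophyly_split_in_tree"]
                    else "split absent from NJ tree"
                )
            )
    return "\n".join(lines)
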