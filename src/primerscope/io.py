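"""File formats, run configuration, and the end-to-end report pipeline.

Tables are TSV, nested reports JSON; every output file carries the hash of
the exact configuration that produced it, so re-running with the same config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bias import (
    CommunityProfile,
    EfficiencyModel,
    bias_report,
    cluster_mismatches_from_coverage,
    simulate_clone_library,
    simulate_qpcr,
)
from .coverage import CoverageCell, CoverageSummary, coverage_table, summarize_library
from .pcr import in_silico_pcr
from .primers import DegeneratePrimer, PrimerSet, default_primer_sets
from .sequences import TargetSequence
from .synth import PRESET_LIBRARY_SIZES, make_community, make_dataset, preset_specs

__all__ = [
    "ConfigError",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "join_clusters",
    "write_clusters",
    "load_primer_sets",
    "write_default_primer_yaml",
    "load_community",
    "RunConfig",
    "run_report",
]

log = logging.getLogger("primerscope")

#: Clusters counted as genuine AOB targets in library summaries.
TARGET_CLUSTERS = ("6A", "7", "0", "other-AOB")


class ConfigError(ValueError):
    """Invalid or missing configuration (CLI exit code 2)."""


class FormatError(ValueError):
    """Malformed input file (CLI exit code 3)."""


# -- FASTA / TSV ------------------------------------------------------------


def read_fasta(path: str | Path, gene: str) -> list[TargetSequence]:
    """Read a multi-FASTA into cluster-less target sequences.

    IDs must be unique; sequences are upper-cased with ambiguity letters
    preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or unparseable FASTA")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        out.append(TargetSequence(id=rec.id, gene=gene, sequence=str(rec.seq)))
    return out


def write_fasta(path: str | Path, sequences: list[TargetSequence]) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def join_clusters(
    sequences: list[TargetSequence], tsv_path: str | Path
) -> list[TargetSequence]:
    """Left-join cluster annotations onto sequences.

    The TSV must have a (sequence_id, cluster) header.  Sequences without an
    annotation are flagged ``unassigned`` (and should be excluded from
    coverage); TSV rows naming unknown IDs produce a warning, not an error.
    Order-invariant in the TSV row order.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, comment="#")
    for col in ("sequence_id", "cluster"):
        if col not in df.columns:
            raise FormatError(f"{tsv_path}: missing column {col!r}")
    mapping = dict(zip(df["sequence_id"], df["cluster"]))
    known = {s.id for s in sequences}
    for unknown in sorted(set(mapping) - known):
        log.warning("cluster TSV references unknown sequence ID %r", unknown)
    n_unassigned = 0
    for s in sequences:
        if s.id in mapping:
            s.cluster = mapping[s.id]
        else:
            s.cluster = "unassigned"
            n_unassigned += 1
    if n_unassigned:
        log.info("%d sequences without cluster annotation (flagged unassigned)",
                 n_unassigned)
    return sequences


def assigned(sequences: list[TargetSequence]) -> list[TargetSequence]:
    """Drop sequences flagged unassigned (the coverage-stage exclusion)."""
    return [s for s in sequences if s.cluster not in (None, "unassigned")]


def write_clusters(path: str | Path, sequences: list[TargetSequence]) -> None:
    pd.DataFrame(
        [{"sequence_id": s.id, "cluster": s.cluster} for s in sequences]
    ).to_csv(path, sep="\t", index=False)


# -- Primer configuration ---------------------------------------------------


def load_primer_sets(source: str | Path) -> dict[str, PrimerSet]:
    """Load primer-set definitions.

    ``source`` is a YAML path, or the literal ``"builtin"`` to opt into the
    packaged transcriptions of the two AOB assays.  There is deliberately no
    silent default: primer definitions are configuration.
    """
    if str(source) == "builtin":
        return default_primer_sets()
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"primer config {path} does not exist")
    data = yaml.safe_load(path.read_text())
    if not data or "primer_sets" not in data:
        raise ConfigError(f"{path}: no 'primer_sets' key")
    sets = {}
    for entry in data["primer_sets"]:
        try:
            forwards = tuple(
                DegeneratePrimer(p["name"], p["sequence"], "forward")
                for p in entry["forwards"]
            )
            reverse = DegeneratePrimer(
                entry["reverse"]["name"], entry["reverse"]["sequence"], "reverse"
            )
            ps = PrimerSet(
                name=entry["name"],
                forwards=forwards,
                reverse=reverse,
                target_gene=entry["target_gene"],
                amplicon_length_bounds=tuple(entry["amplicon_length_bounds"]),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{path}: bad primer set entry: {exc}") from exc
        sets[ps.name] = ps
    return sets


def write_default_primer_yaml(path: str | Path) -> None:
    """Write the packaged primer definitions as an editable YAML config."""
    sets = default_primer_sets()
    data = {
        "primer_sets": [
            {
                "name": ps.name,
                "target_gene": ps.target_gene,
                "amplicon_length_bounds": list(ps.amplicon_length_bounds),
                "forwards": [
                    {"name": p.name, "sequence": p.sequence} for p in ps.forwards
                ],
                "reverse": {"name": ps.reverse.name, "sequence": ps.reverse.sequence},
            }
            for ps in sets.values()
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def primer_set_for_gene(sets: dict[str, PrimerSet], gene: str) -> PrimerSet:
    for ps in sets.values():
        if ps.target_gene == gene:
            return ps
    raise ConfigError(f"no primer set configured for gene {gene!r}")


# -- Community / model configuration ----------------------------------------


def load_community(path: str | Path) -> CommunityProfile:
    """Load a community profile from YAML (cells, optional copy numbers)."""
    data = yaml.safe_load(Path(path).read_text())
    if not data or "cells" not in data:
        raise ConfigError(f"{path}: community YAML needs a 'cells' mapping")
    try:
        return CommunityProfile(
            cells={str(k): float(v) for k, v in data["cells"].items()},
            copies_per_cell={
                str(k): int(v)
                for k, v in data.get("copies_per_cell", {"16S": 1, "amoA": 2}).items()
            },
            per_cluster_copies=data.get("per_cluster_copies", {}),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


# -- Coverage table serialization --------------------------------------------


def write_coverage_tsv(path: str | Path, summary: CoverageSummary, config_hash: str) -> None:
    df = summary.to_tidy()
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        fh.write(f"# primer_set: {summary.primer_set_name} gene: {summary.gene} "
                 f"n_input: {summary.n_input}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> CoverageSummary:
    """Rebuild a CoverageSummary from its tidy TSV (for the simulate command)."""
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in ("primer_set:", "gene:", "n_input:"):
                if token in line:
                    key = token.rstrip(":")
                    header[key] = line.split(token)[1].split()[0]
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse coverage TSV: {exc}") from exc
    if df.empty or not {"cluster", "role", "mismatches", "count"} <= set(df.columns):
        raise FormatError(f"{path}: not a coverage TSV")
    cells: dict[tuple[str, str], CoverageCell] = {}
    labels: dict[str, str] = {}
    for row in df.itertuples(index=False):
        cell = cells.setdefault((str(row.cluster), row.role), CoverageCell())
        cell.n_sequences += int(row.count)
        cell.histogram[int(row.mismatches)] += int(row.count)
        labels[row.role] = row.primer
    return CoverageSummary(
        primer_set_name=header.get("primer_set", "unknown"),
        gene=header.get("gene", "unknown"),
        primer_labels=labels,
        cells=cells,
        unavailable={},
        n_input=int(header.get("n_input", sum(c.n_sequences for c in cells.values()))),
    )


# -- Run configuration and the end-to-end report ------------------------------


@dataclass
class RunConfig:
    """Everything an end-to-end report run depends on; fully serializable."""

    preset: str = "islevbro-like"
    primers: str = "builtin"
    max_mismatch: int = 3
    model: EfficiencyModel = field(default_factory=EfficiencyModel)
    mismatch_statistic: str = "mean"
    n_pcr_cycles: int = 30
    seed: int = 0
    scale: int = 1
    out_dir: str = "primerscope-report"

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "primers": str(self.primers),
            "max_mismatch": self.max_mismatch,
            "model": self.model.to_dict(),
            "mismatch_statistic": self.mismatch_statistic,
            "n_pcr_cycles": self.n_pcr_cycles,
            "seed": self.seed,
            "scale": self.scale,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _r6(x: float) -> float:
    return float(f"{x:.6g}")


def run_report(config: RunConfig) -> dict:
    """Run the full workflow for one scenario preset and write the bundle.

    Stages: synthetic dataset -> coverage tables (both genes) -> per-cluster
    efficiencies -> qPCR bias comparison -> clone-library simulation ->
    library composition summaries.  Outputs: ``coverage_<gene>.tsv``,
    ``bias.json``, ``libraries.tsv``, ``summary.txt`` and a ``MANIFEST.json``
    of completed stages (written even on failure).
    """
    if config.preset not in PRESET_LIBRARY_SIZES:
        raise ConfigError(
            f"report preset must be one of {sorted(PRESET_LIBRARY_SIZES)}, "
            f"got {config.preset!r}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    manifest: dict = {"config": config.to_dict(), "config_hash": chash, "stages": []}
    bundle: dict = {"config": config}

    try:
        primer_sets = load_primer_sets(config.primers)
        summaries: dict[str, CoverageSummary] = {}
        mismatches: dict[str, dict[str, tuple[int, int]]] = {}
        for gene in ("16S", "amoA"):
            ps = primer_set_for_gene(primer_sets, gene)
            specs = preset_specs(
                config.preset, gene, base_seed=config.seed * 1000 + (0 if gene == "16S" else 500),
                scale=config.scale,
            )
            seqs, ledger = make_dataset(specs, ps)
            log.info("%s: generated %d %s sequences", config.preset, len(seqs), gene)
            summary = coverage_table(seqs, ps, max_mismatch_scan=6)
            summaries[gene] = summary
            mismatches[gene] = cluster_mismatches_from_coverage(
                summary, statistic=config.mismatch_statistic
            )
            write_coverage_tsv(out / f"coverage_{gene}.tsv", summary, chash)
            manifest["stages"].append(f"coverage_{gene}")

        community = make_community(config.preset)
        est16 = simulate_qpcr(community, mismatches["16S"], config.model, "16S")
        esta = simulate_qpcr(community, mismatches["amoA"], config.model, "amoA")
        report = bias_report(est16, esta)
        manifest["stages"].append("bias")

        libraries = {}
        lib_summaries = {}
        for gene, est in (("16S", est16), ("amoA", esta)):
            n_clones = PRESET_LIBRARY_SIZES[config.preset][gene]
            lib = simulate_clone_library(
                community, mismatches[gene], config.model, gene,
                n_clones=n_clones, seed=config.seed * 10 + (1 if gene == "16S" else 2),
                n_pcr_cycles=config.n_pcr_cycles,
                name=f"{config.preset}-{gene}",
            )
            libraries[gene] = lib
            lib_summaries[gene] = summarize_library(lib, TARGET_CLUSTERS)
        manifest["stages"].append("libraries")

        lib_rows = []
        for gene, lib in libraries.items():
            for cluster, count in sorted(Counter(lib.labels).items()):
                lib_rows.append(
                    {"library": lib.name, "gene": gene, "cluster": cluster,
                     "count": count, "percent": _r6(100.0 * count / lib.n)}
                )
        with open(out / "libraries.tsv", "w") as fh:
            fh.write(f"# config_hash: {chash}\n")
            pd.DataFrame(lib_rows).to_csv(fh, sep="\t", index=False)

        bias_payload = {
            "config_hash": chash,
            "parameters": {**config.model.to_dict(),
                           "mismatch_statistic": config.mismatch_statistic,
                           "n_pcr_cycles": config.n_pcr_cycles,
                           "mismatch_inputs": {
                               g: {c: list(v) for c, v in mm.items()}
                               for g, mm in mismatches.items()
                           }},
            "estimates": {
                g: {
                    "apparent_copies": _r6(e.apparent_copies),
                    "corrected_cells": _r6(e.corrected_cells),
                    "copies_per_cell": e.copies_per_cell_used,
                }
                for g, e in (("16S", est16), ("amoA", esta))
            },
            "true_cells": _r6(community.total_cells),
            "ratio_16s_over_amoa": (None if report.infinite else _r6(report.ratio)),
            "infinite_ratio": report.infinite,
            "per_cluster": {
                c: {k: _r6(v) for k, v in d.items()}
                for c, d in report.per_cluster.items()
            },
            "libraries": {
                g: {
                    "n": s.n,
                    "percent_non_target": _r6(s.percent_non_target),
                    "composition": {
                        r.cluster: _r6(r.percent) for r in s.table.itertuples()
                    },
                }
                for g, s in lib_summaries.items()
            },
        }
        (out / "bias.json").write_text(json.dumps(bias_payload, indent=2) + "\n")
        manifest["stages"].append("bias.json")

        ratio_txt = "inf" if report.infinite else f"{report.ratio:.3g}"
        lines = [
            f"primerscope report  (config {chash})",
            f"preset: {config.preset}   seed: {config.seed}",
            f"model: e0={config.model.e0} rho={config.model.rho} "
            f"rho3={config.model.rho3} n_q={config.model.n_q} "
            f"n_pcr_cycles={config.n_pcr_cycles} "
            f"statistic={config.mismatch_statistic}",
            f"true cells: {community.total_cells:.3g}",
            f"16S corrected cells:  {est16.corrected_cells:.4g}",
            f"amoA corrected cells: {esta.corrected_cells:.4g}",
            f"16S/amoA abundance ratio: {ratio_txt}",
        ]
        for gene, s in lib_summaries.items():
            comp = ", ".join(
                f"{r.cluster} {r.percent:.1f}%" for r in s.table.itertuples()
            )
            lines.append(f"{gene} clone library (n={s.n}): {comp} "
                         f"[non-target {s.percent_non_target:.1f}%]")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        manifest["stages"].append("summary")

        bundle.update(
            coverage=summaries, mismatches=mismatches, community=community,
            estimates={"16S": est16, "amoA": esta}, report=report,
            libraries=libraries, library_summaries=lib_summaries,
        )
        return bundle
    finally:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")


def pcr_table(
    sequences: list[TargetSequence], primer_set: PrimerSet, max_mismatch: int
) -> pd.DataFrame:
    """One in-silico-PCR row per template (the ``pcr`` subcommand's payload)."""
    rows = []
    for seq in sequences:
        res = in_silico_pcr(seq, primer_set, max_mismatch=max_mismatch)
        if res:
            rows.append({
                "template_id": seq.id, "status": "amplicon",
                "fwd_start": res.forward_match.start,
                "rev_start": res.reverse_match.start,
                "fwd_mismatches": res.forward_match.mismatch_total,
                "rev_mismatches": res.reverse_match.mismatch_total,
                "fwd_three_prime": res.forward_match.three_prime_mismatches,
                "rev_three_prime": res.reverse_match.three_prime_mismatches,
                "inter_primer_length": res.inter_primer_length,
                "total_length": res.total_length,
            })
        else:
            rows.append({"template_id": seq.id, "status": res.reason})
    columns = ["template_id", "status", "fwd_start", "rev_start",
               "fwd_mismatches", "rev_mismatches", "fwd_three_prime",
               "rev_three_prime", "inter_primer_length", "total_length"]
    return pd.DataFrame(rows, columns=columns)
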