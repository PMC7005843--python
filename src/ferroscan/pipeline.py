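"""High-level orchestration: input files -> annotations -> calls -> summaries."""

from __future__ import annotations

from pathlib import Path

from . import sequence_io, summarize
from .annotate import GeneAnnotation, annotate_sample, write_annotations_csv
from .family_db import FamilyDatabase, default_database
from .neighborhoods import (
    CategoryCall,
    RuleSet,
    apply_rules,
    build_neighborhoods,
)
from .sequence_io import SampleInput


def run_sample(
    sample: SampleInput,
    db: FamilyDatabase | None = None,
    ruleset: RuleSet | None = None,
    max_gap: int | None = None,
) -> tuple[list[GeneAnnotation], list[CategoryCall]]:
    """Annotate one sample and evaluate the category rules."""
    db = db or default_database()
    annotations = annotate_sample(sample, db)
    nbs = build_neighborhoods(annotations, max_gap=max_gap)
    calls = apply_rules(nbs, db, ruleset=ruleset, sample_id=sample.sample_id)
    return annotations, calls


def load_sample(path: str | Path, input_type: str = "protein") -> SampleInput:
    """Load one input file as a sample (protein FASTA, GenBank, or contigs)."""
    path = Path(path)
    if input_type == "protein":
        return sequence_io.read_protein_calls(path)
    if input_type == "genbank":
        return sequence_io.read_genbank_calls(path)
    if input_type == "contigs":
        contigs = sequence_io.read_contigs(path)
        return sequence_io.call_genes_external(contigs, sample_id=path.stem)
    raise ValueError(f"unknown input type {input_type!r}")


def run_files(
    paths: list[str | Path],
    outdir: str | Path,
    input_type: str = "protein",
    db: FamilyDatabase | None = None,
    max_gap: int | None = None,
    bootstrap_b: int = 0,
    seed: int = 0,
    render_figures: bool = False,
) -> dict:
    """Annotate a set of input files and write all comparative outputs."""
    db = db or default_database()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    results = []
    ann_csv = outdir / "annotations.csv"
    if ann_csv.exists():
        ann_csv.unlink()
    all_calls: list[CategoryCall] = []
    for i, path in enumerate(paths):
        sample = load_sample(path, input_type=input_type)
        annotations, calls = run_sample(sample, db=db, max_gap=max_gap)
        write_annotations_csv(annotations, sample.sample_id, ann_csv, append=i > 0)
        results.append((sample, calls))
        all_calls.extend(calls)

    matrix = summarize.count_matrix(results)
    orf_counts = {s.sample_id: s.orf_count for s, _ in results}
    normalized = summarize.normalize(matrix, orf_counts)
    dendrogram = None
    if matrix.shape[1] >= 2:
        scaled = summarize.scale_rows(normalized)
        dendrogram = summarize.ward_cluster(scaled, seed=seed, bootstrap_b=bootstrap_b)
    written = summarize.export(
        matrix, dendrogram, all_calls, outdir,
        normalized=normalized, render_figures=render_figures,
    )
    written["annotations"] = ann_csv
    return {
        "matrix": matrix,
        "normalized": normalized,
        "dendrogram": dendrogram,
        "written": written,
        "samples": results,
    }
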