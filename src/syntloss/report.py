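"""Genome-report arithmetic: assembly ladder, annotation percentages, survey size."""

from __future__ import annotations

from .survey import SurveyEstimate, assembly_stats, proportion_percent


def genome_report(
    assembly_lengths: list[int],
    busco: tuple[int, int] | None = None,
    annotated_genes: tuple[int, int] | None = None,
    repeat_bp: int | None = None,
    survey: SurveyEstimate | None = None,
) -> dict[str, float | int]:
    """Key/value summary lines mirroring a genome-paper statistics table.

    ``busco`` and ``annotated_genes`` are (count, total searched) pairs;
    ``repeat_bp`` is the summed repeat length, reported as a percentage
    of the assembly total.
    """
    stats = assembly_stats(assembly_lengths)
    report: dict[str, float | int] = {
        "n_seqs": stats.n_seqs,
        "total_len": stats.total_len,
        "max_len": stats.max_len,
    }
    for level, (length, count) in sorted(stats.nxx.items()):
        report[f"n{level}"] = length
        report[f"n{level}_count"] = count
    if busco is not None:
        report["complete_pct"] = proportion_percent(*busco)
    if annotated_genes is not None:
        report["annotated_pct"] = proportion_percent(*annotated_genes)
    if repeat_bp is not None:
        report["repeat_pct"] = proportion_percent(repeat_bp, stats.total_len)
    if survey is not None:
        report["survey_total_kmers"] = survey.total_kmers
        report["survey_peak_depth"] = survey.peak_depth
        report["survey_genome_size_bp"] = survey.genome_size_bp
    return report
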