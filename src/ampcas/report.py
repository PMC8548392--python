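"""Plain-text (and minimal HTML) report rendering.

The centrepiece is the top-10 indel alignment table: each mutant allele is
rendered against the wild-type amplicon with dashes across deleted spans
and inserted bases marked at their anchor, with the PAM, protospacer and
expected cut site annotated above the reference.
"""

from __future__ import annotations

from html import escape

from .calling import IndelEvent, SampleCallSet, callset_summary
from .guides import TargetSite
from .zygosity import CohortSummary, _type_str


def _annotation_line(site: TargetSite, length: int) -> str:
    """PAM ``###``, protospacer ``=``, cut site ``^`` above the reference."""
    marks = [" "] * length
    ps, pe = site.pam_interval
    for i in range(ps, min(pe, length)):
        marks[i] = "#"
    if site.strand == "+":
        proto = (pe, pe + len(site.spacer))
    else:
        proto = (ps - len(site.spacer), ps)
    for i in range(max(proto[0], 0), min(proto[1], length)):
        marks[i] = "="
    if 0 < site.cut_center < length:
        marks[site.cut_center] = "^"
    return "".join(marks)


def render_allele(amplicon: str, event: IndelEvent) -> str:
    """Render one mutant allele against the reference coordinate frame."""
    if event.kind == "del":
        return amplicon[: event.start] + "-" * event.length + amplicon[event.end :]
    return (
        amplicon[: event.start]
        + "[+" + event.inserted.lower() + "]"
        + amplicon[event.start :]
    )


def render_indel_table(
    amplicon: str,
    site: TargetSite,
    types: list[tuple[IndelEvent, int]],
    top_k: int = 10,
    flank: int = 20,
) -> str:
    """Fig-style alignment of the most abundant indel types around the cut."""
    lo = max(0, min(site.window[0], site.pam_interval[0]) - flank)
    hi = min(len(amplicon), site.window[1] + flank)
    lines = [
        "# = PAM   = protospacer   ^ expected cut",
        _annotation_line(site, len(amplicon))[lo:hi],
        amplicon[lo:hi] + "  wild type",
    ]
    if not types:
        lines.append("(no retained indel types)")
        return "\n".join(lines)
    for ev, count in types[:top_k]:
        allele = render_allele(amplicon, ev)
        # insertions stretch the frame; clip deletions to the same window
        if ev.kind == "del":
            shown = allele[lo:hi]
        else:
            shown = allele[lo : hi + len(ev.inserted) + 4]
        lines.append(f"{shown}  {_type_str(ev)} n={count}")
    return "\n".join(lines)


def render_report(
    site: TargetSite,
    amplicon: str,
    callsets: list[SampleCallSet] | None = None,
    cohort: CohortSummary | None = None,
    title: str = "ampcas report",
) -> str:
    """Render per-sample frequency tables, cohort zygosity counts, and the
    top-10 indel alignment as plain text."""
    if callsets is None and cohort is None:
        raise ValueError("render_report needs at least one summary")
    out: list[str] = [title, "=" * len(title), ""]
    out.append(f"site {site.amplicon_id}: PAM {site.pam.pattern} at "
               f"{site.pam_interval[0] + 1}-{site.pam_interval[1]} ({site.strand}), "
               f"cut centre {site.cut_center}, window "
               f"{site.window[0] + 1}-{site.window[1]}")
    out.append("")

    type_counts: dict[IndelEvent, int] = {}
    if callsets:
        out.append("Per-sample indel frequencies")
        out.append("-" * 28)
        for cs in callsets:
            s = callset_summary(cs)
            ratio = "saturated" if cs.saturated else f"{cs.frequency_ratio:.4g}"
            out.append(
                f"  {cs.sample_id}: {cs.mutant_reads}/{cs.aligned_reads} mutant reads "
                f"({cs.frequency_pct:.2f}%), mutant/wild-type ratio {ratio}, "
                f"{s['n_types_retained']}/{s['n_types_observed']} types retained"
            )
            for ev, rt in cs.retained.items():
                type_counts[ev] = type_counts.get(ev, 0) + rt.count
        out.append("")

    if cohort is not None:
        out.append("Cohort zygosity")
        out.append("-" * 15)
        out.append(f"  plants called: {cohort.n_plants} "
                   f"(+{cohort.n_insufficient} with insufficient coverage)")
        for cls, n in cohort.counts.items():
            out.append(f"  {cls}: {n}")
        out.append(f"  edited (het+hom): {cohort.n_edited} ({cohort.pct_edited:.1f}%)")
        if not cohort.n_edited:
            out.append("  no edited plants: zygosity proportions not defined")
        for t, n, share in cohort.top_types:
            type_counts[t] = type_counts.get(t, 0) + n
        out.append("")

    ranked = sorted(type_counts.items(), key=lambda kv: (-kv[1], kv[0].start))
    out.append("Top indel alignment")
    out.append("-" * 19)
    out.append(render_indel_table(amplicon, site, ranked))
    out.append("")
    return "\n".join(out)


def render_html(text_report: str, title: str = "ampcas report") -> str:
    return (
        "<!doctype html><html><head><meta charset='utf-8'>"
        f"<title>{escape(title)}</title></head>"
        f"<body><pre>{escape(text_report)}</pre></body></html>"
    )
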