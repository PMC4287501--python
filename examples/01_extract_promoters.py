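"""Identify promoters from long reads: length filter, coding-hit filter,
upstream extraction, de-redundancy.

Builds a small synthetic read set whose per-read fate is known by
construction, runs the extraction pipeline and prints the stage-by-stage
survivor counts.
"""

from metaregulome import extract_promoters, generate_read_fixture

fixture = generate_read_fixture(seed=42)
promoters, report, clusters = extract_promoters(fixture.reads, fixture.hits)

print("stage-by-stage survivor counts:")
for stage, count in report.as_rows():
    print(f"  {stage:28s} {count}")
print()
print(f"rejections: {report.rejection_reasons}")
print()
for p in promoters[:3]:
    print(f"  {p.id}  ({p.strand} strand, gene {p.gene_subject})  {p.sequence[:40]}...")
print()
print(
    "Each surviving promoter is exactly 300 nt, read 5'->3' into its gene;\n"
    "the counts shrink at every filter (too-short reads, weak protein hits,\n"
    "insufficient non-coding upstream, near-duplicate collapse at 98%)."
)
assert dict(report.as_rows()) == fixture.expected_counts, "fixture truth mismatch"
print("\npipeline output matches the generator's planted truth exactly.")
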