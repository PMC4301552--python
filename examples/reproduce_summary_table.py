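"""Reproduce the pooled-OR summary table from the bundled CRP corpus.

For each variant, every genetic contrast is pooled overall and within each
cancer-type stratum. Cells read "OR (95% CI)" with the Cochran-Q
heterogeneity p-value alongside: an OR above 1 means carriers of the
variant genotype class are over-represented among cases; P_h >= 0.05 means
the studies are mutually consistent and a fixed-effect model was used.
"""

from genemeta import builtin_fixture, format_report, run_meta, total_counts

for variant in ("rs2808630", "rs1417938"):
    studies = builtin_fixture(variant)
    n_cases, n_controls = total_counts(studies)
    print(f"\n{variant}: {len(studies)} study arms, "
          f"{n_cases:,} cases / {n_controls:,} controls")
    print(format_report(run_meta(studies)))
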