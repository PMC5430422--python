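"""Reproduce the published pooled causal estimates from the packaged tables.

Parses the two handgrip instruments and the eight outcome tables, converts
each printed odds ratio and 95% CI to a log-scale effect with a CI-derived
standard error, harmonizes alleles, pools per-SNP Wald ratios with
fixed-effect IVW, and prints the result next to the published values.
"""

from gripmr import reproduce_headline

report = reproduce_headline(phenotype_sd=3.4)

print(report.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nRecomputed vs published pooled estimates (|diff| reflects the")
print("two-decimal rounding of the printed per-SNP inputs):")
print(report.comparison.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

inst = report.instruments
print(
    f"\nInstruments: K={inst.k}, n={inst.n}. Literal R^2={inst.r2_total:.4f} "
    f"gives F={inst.f_stat:.0f}; rescaled by a 3.4 kg phenotype SD, "
    f"R^2={inst.r2_total_adjusted:.4f} gives F={inst.f_stat_adjusted:.0f} "
    f"(the published joint F is 128)."
)
print(
    "\nAn OR below 1 for CAD/MI means each genetically proxied 1-kg increase "
    "in grip strength lowers disease odds."
)
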