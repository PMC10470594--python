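"""Stage accounting with integer percentages.

The accounting report tracks a single-cell study's attrition: cells
processed, cells yielding sequence, on-target (fungal) cells, and cells
retained for phylogenetic analysis, with percentages of the processed
total rounded half-up.
"""

from scoperon import accounting

report = accounting((259, 139, 129, 127))
print(f"processed cells          : {report.n_processed_cells}")
print(f"with sequence            : {report.n_with_sequence} ({report.pct_with_sequence}%)")
print(f"fungal (on-target)       : {report.n_fungal} ({report.pct_fungal}%)")
print(f"retained for phylogeny   : {report.n_retained_for_phylogeny} ({report.pct_retained}%)")
print()
print("139/259 = 53.7% prints as 54%: percentages are rounded half-up, and")
print("counts are validated to be non-increasing through the stages.")
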