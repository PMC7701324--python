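"""Encode a sequence into position-specific (gapped) k-mer indicators.

Builds a short RNA sequence, slides two patterns along it, and shows the
binary indicator strings plus the GC-content feature and the size of the
full descriptor space for 41-nt windows.
"""

from psgkmer import gc_content, indicator_string, parse_template
from psgkmer.encoder import descriptor_counts

seq = "ACGGCGGUG"
for template in ("GG", "ACG", "A--CG"):
    pattern = parse_template(template)
    bits = indicator_string(pattern, seq)
    print(f"pattern {template!r:8} on {seq}: {bits}")
# Each digit is one window position: 1 where the pattern's fixed
# nucleotides match (gaps match anything), 0 elsewhere.

print(f"GC content of {seq}: {gc_content(seq):.2f}%")

counts = descriptor_counts(41)
print("descriptor space for 41-nt windows:")
for ft in sorted(counts, key=lambda t: int(t[2:])):
    print(f"  {ft}: {counts[ft]}")
print(f"  total: {sum(counts.values())} features "
      "(19,876 binary indicators + GC)")
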