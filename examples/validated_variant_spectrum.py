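"""Mutational spectrum of the 22 validated somatic variants.

Builds the pyrimidine-collapsed 6-class and 96-channel spectra from the
packaged variant table (trinucleotide flanks are synthetic stand-ins
consistent with the published CpG counts), and correlates the 96-channel
spectrum against a synthetic signature matrix to show the interface.
"""

import brainmosaic as bm
from brainmosaic.spectra import random_signature_matrix, signature_correlation

table = bm.load_table1()
spec = bm.build_spectrum(
    list(zip(table["ref"], table["alt"], table["context_synthetic"]))
)
print("6-class spectrum (counts):")
print(spec.six_class.to_string())
pct = 100 * spec.n_transitions / spec.n_variants
print(f"\ntransitions: {spec.n_transitions}/{spec.n_variants} ({pct:.1f}%), "
      f"transversions: {spec.n_transversions}")

n_cpg, n_ct, frac = bm.cpg_fraction(
    zip(table["ref"], table["alt"], table["context_synthetic"])
)
print(f"C>T variants at CpG sites: {n_cpg}/{n_ct} ({100 * frac:.1f}%)")
print("  (C>T at methylated CpG is the classic deamination footprint)")

sigs = random_signature_matrix(k=5, seed=0)
corr = signature_correlation(spec, sigs)
print("\nPearson correlation against 5 synthetic signatures (best first):")
print(corr.round(4).to_string(index=False))
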