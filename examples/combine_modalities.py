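"""Integrate per-modality scores into a cancer call, and screening arithmetic.

Shows Stouffer/Fisher integration of three modality scores, the behaviour
when modalities are missing, predictive values at two prevalences, and the
longitudinal score delta used for treatment monitoring.
"""

from ctdetect import ModalityScore, combine_modalities, score_change, screening_performance

cna = ModalityScore("cna", k_significant=3, z=2.8, p=0.0026)
snv = ModalityScore("snv", k_significant=0, z=0.0, p=0.5)   # neutral modality
meth = ModalityScore("meth", k_significant=5, z=3.4, p=0.00034)

for method in ("stouffer", "fisher"):
    res = combine_modalities([cna, snv, meth], method=method)
    print(f"{method:9s}: z = {res.z:.3f}, p = {res.p:.4g}, call = {res.call}")

two = combine_modalities([cna, meth])
print(f"cna+meth only: z = {two.z:.3f}, p = {two.p:.4g} "
      "(the method tolerates missing modalities)")

sp = screening_performance(sensitivity=0.852, specificity=0.888, prevalence=0.067)
print(f"\nat 6.7% prevalence: NPV = {100 * sp.npv:.1f}%, PPV = {100 * sp.ppv:.1f}%")
sp = screening_performance(0.852, 0.888, 0.03)
print(f"at 3.0% prevalence: NPV = {100 * sp.npv:.1f}%, "
      f"post-test risk after a negative result = {100 * sp.post_test_negative:.1f}%")

print(f"\ntreatment monitoring: a 16.86 -> 4.34 score drop is a "
      f"{score_change(16.86, 4.34):.0f}% tumour-burden reduction")
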