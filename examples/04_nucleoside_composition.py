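"""Assign LC-MS nucleoside peaks and compute percent deoxycytidine composition.

Simulates a peak table for DNA whose cytosines are 70 % hydroxymethylated and
20 % formylated (plus residual dC and 5me-dC), then recovers the composition
by matching observed m/z to [M+H]+ / [M+Na]+ adducts within 0.025 Da and
combining the two adduct intensities per nucleoside.
"""

from densigrad import MsSimSpec, composition_percent, match_peaks, simulate_ms_peaks

spec = MsSimSpec(composition=(5, 5, 70, 20, 0), mass_error_sd=0.005, seed=3)
peaks = simulate_ms_peaks(spec)
print(f"simulated {len(peaks)} peaks, e.g. m/z {peaks[0].mz:.4f} at {peaks[0].intensity:.0f} counts")

assigned, unassigned = match_peaks(peaks, tol=0.025)
print(f"assigned {len(assigned)} peaks, {len(unassigned)} unassigned")

result = composition_percent(assigned, unassigned)
for name, pct in result.percentages.items():
    if pct:
        print(f"  {name:>7}: {pct:5.1f} % of total deoxycytidines")
# Percentages are over the five dC forms only; dG/dA/dT peaks would simply
# stay unassigned.
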