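"""Injection-order batch effects: random vs continuous injection.

The same quartet design is simulated under three injection schemes with
instrument drift switched on: RI scatters runs randomly over a long time
window, CI1 interleaves the groups cycle by cycle, CI2 injects each group as
a consecutive block. Random injection lets drift act within replicate
groups, inflating the noise and collapsing the SNR toward 0 dB; grouped
continuous injection keeps replicates adjacent and the SNR high.
"""

import numpy as np

import proteoqc as pq

for mode in ("RI", "CI1", "CI2"):
    snrs = []
    for seed in range(5):
        config = pq.SimulationConfig(n_proteins=800, injection_mode=mode,
                                     drift_per_injection=1.06,
                                     seed=10 + seed)
        matrix, metadata, _ = pq.simulate_experiment(config)
        fot = pq.ibaq_to_fot(matrix)
        snrs.append(pq.snr_for_experiment(fot, metadata).snr_db)
    print(f"{mode:>3}: mean SNR over 5 seeds = {np.mean(snrs):6.2f} dB "
          f"({pq.classify_snr(float(np.mean(snrs)))})")
print("random injection under drift degrades quantitative quality; the "
      "grouped continuous mode is most robust")
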