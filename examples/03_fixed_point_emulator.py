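"""Quantize a trained configuration and run the integer-only sorter.

The on-implant sorter stores 5-bit feature indices, 7-bit window bounds and
3-bit class ids in shared register banks, and classifies with bare integer
comparators.  This example quantizes a float configuration, verifies that
the fixed-point path agrees with the float path, and prints the register-
bank memory budget for the full 512-class hardware.
"""

import numpy as np

import salientsort as ss

matrix, _ = ss.simulate_channel(
    {"n_units": 3, "n_spikes": 750, "snr": 8.0, "seed": 42})
result = ss.train_channel(matrix, L=2, seed=42)

test = ss.SpikeMatrix(matrix.waveforms[result.test_indices],
                      matrix.labels[result.test_indices])
int_labels = ss.emulate_sort(test, result.quantized_config)
agreement = np.mean(int_labels == result.predictions)
print(f"float vs fixed-point label agreement: {agreement:.4f}")

image = result.quantized_config.register_image(ss.BitWidths())
print(f"register image ({len(image) * 4} bits): {image}")

report = ss.memory_report(ss.RegisterBanks(), ss.BitWidths())
kib = report["per_bank_kibit"]
print(f"512-class banks: index {kib['index']:.0f} kibit, "
      f"bounds {kib['bound']:.0f} kibit, class ids {kib['classid']:.0f} kibit "
      f"(total {kib['total']:.0f} kibit)")

# Quantization rounds windows outward, so the integer path can only add
# borderline matches relative to the float path, never drop a correct one.
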