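"""Recover the cyclin degradation rate from noisy data by replica exchange.

Generates a noisy wild-type G2-M time course (known sigma), then runs
four Metropolis replicas at different inverse temperatures with
mixed-scale step proposals and adjacent-pair exchanges. The
minimum-energy sample should land close to the generating value
k_d = 0.008 even when the chain starts 2.5x off.
"""

import numpy as np

import sifkit as sk

model = sk.g2m_model()
times = np.linspace(0.0, 30.0, 21)
reference = sk.generate_reference_timecourse(
    model, times, noise_sigma=0.02, seed=11, species=("CycB", "MPF"))
print(f"reference: {len(reference)} noisy observations, sigma = 0.02")

energy = sk.make_chisq_energy(model, reference)
start = dict(model.params, k_d=0.02)  # 2.5x the true value
result = sk.run_remc(energy, start, ["k_d"], betas=[0.25, 0.5, 1.0, 2.0],
                     n_iter=1200, swap_interval=10, seed=5,
                     e_min=-4, e_max=-2)

true_kd = model.params["k_d"]
best = result.best_params["k_d"]
print(f"true k_d = {true_kd}, recovered = {best:.5f} "
      f"({abs(best - true_kd) / true_kd:.1%} off)")
print(f"best chi-squared = {result.best_energy:.1f} over {len(reference)} "
      "residuals (values near the residual count indicate a noise-level fit)")
print(f"swap acceptance rate = {result.swap_rate:.2f}; "
      f"move acceptance per replica = "
      f"{[round(a, 2) for a in result.move_acceptance]}")
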