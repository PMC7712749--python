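"""Small entropy-maximization demo.

Optimizes passive-storage traits on a shortened horizon (60 days) with a
few Latin-hypercube restarts so the example finishes in about a minute.
The printed numbers are the best cumulative entropy found and the trait
values that achieve it; production analyses use horizon=None (the full two
years), 90 restarts, and the default evaluation budget.
"""

from mepweb import load_scenario, optimize_traits

scen, web = load_scenario("nominal", "passive")
result = optimize_traits(scen, web, restarts=3, seed=1, budget=25,
                         horizon=60.0, rtol=1e-5, atol=1e-6)

print(f"best 60-day sigma_T: {result.best_sigma_t / 1e6:.4f} MJ/K")
print(result.restart_table().to_string(index=False))
tv = result.best_traits
print(f"eps_P = {tv.eps_p[0]:.3f}, Omega_amp = {tv.omega_amp[0]:.3f}, "
      f"eps_B = {tv.eps_b[0]:.3f}")
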