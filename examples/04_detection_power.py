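"""Detection power of z-diff versus naive z-score subtraction.

For each disruption Delta and residual lag correlation rho, the fraction
of simulated patients flagged is compared between the two scores.  The
z-diff false-positive rate stays at the nominal 5% for every rho,
whereas the naive difference of z-scores over-flags healthy subjects at
low rho (~16.6% at rho = 0) and is nominal only at rho = 0.5.
"""

from zdiffkit import SimGrid, analytic_detection_rate, make_reference_model, run_grid

model = make_reference_model(n_train=20_000, sigma2=1.0, omega2=1.0, seed=0)
grid = SimGrid(delta_values=(0.0, 1.0, 2.0), rho_values=(0.0, 0.5, 0.9),
               n_per_cell=10_000, seed=3)
res = run_grid(grid, model)

print("detection rate (simulated | closed form):")
print(f"{'delta':>6} {'rho':>5} {'z-diff':>17} {'naive':>17}")
for rho in grid.rho_values:
    for delta in grid.delta_values:
        rz = res.rate(delta, rho, "zdiff")
        rn = res.rate(delta, rho, "naive")
        az = analytic_detection_rate(delta, rho, method="zdiff")
        an = analytic_detection_rate(delta, rho, method="naive")
        print(f"{delta:6.1f} {rho:5.1f} {rz:8.3f} | {az:6.3f} {rn:8.3f} | {an:6.3f}")
print("\nDelta=0 rows are false-positive rates: z-diff holds 5% at every rho;"
      "\npositive autocorrelation makes true disruptions easier to detect.")

# a figure like the detection-rate panel can be written with:
# from zdiffkit import plot_detection_rates; plot_detection_rates(res, "panel.png")
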