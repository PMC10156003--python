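"""Run the PD-L1 tumor--T-cell model at its nominal parameters.

The model grows a hexagonally packed tumor disc while T cells are
recruited at the rim, migrate inward, kill tumor cells, and are in turn
suppressed by PD-L1.  The printed counts summarize the endpoint mix of
cell states; the tumor radius is the maximum centroid distance in um.
"""

from abmcal import SimConfig, nominal_parameters_ex1, simulate, tumor_radius

params = nominal_parameters_ex1()
cfg = SimConfig()  # 80 steps, 20-um cells, 80-um initial tumor radius

table, state = simulate(params, cfg, seed=1, return_state=True)

print("final cell counts by state:")
print(table["kind"].value_counts().to_string())
print(f"tumor radius: {tumor_radius(state):.0f} um")
print(f"max PD-L1 level reached: {table['pdl1'].max():.5f} (cap {params.pdl1_max})")
# A balanced mix of live tumor, active and suppressed T cells indicates the
# nominal dynamics are in the contested regime the calibration examples use.
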