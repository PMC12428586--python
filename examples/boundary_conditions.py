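"""Allocate an expiratory flow over the 18 lung segments and write
velocity-inlet boundary conditions for the external CFD run.

The per-segment ventilation fractions are fixed; the raw percentages sum
to 99.2 %, so they are renormalized to conserve the total flow.  Each
outlet's inlet velocity is its allocated flow divided by its orifice area.
"""

import airwaykit as ak

table = ak.load_segment_fractions()          # normalized to sum to 1
omap = ak.OutletMap([ak.Outlet(f"o_{seg}", [seg], area_mm2=28.0)
                     for seg in ak.SEGMENT_FRACTIONS_RAW])

total = 2.25  # L/s, the predicted normal FEV1 used as expiratory flow
case = ak.allocate_flows(total, table, omap)

print(f"total flow {total} L/s over {len(omap.outlets)} outlets")
print(f"{'outlet':28s} {'flow L/s':>9s} {'inlet m/s':>10s}")
for oid in list(case.outlet_flows_L_s)[:5]:
    print(f"{oid:28s} {case.outlet_flows_L_s[oid]:9.4f} "
          f"{case.outlet_velocities_m_s[oid]:10.3f}")
print("...")
print(f"sum of outlet flows = {sum(case.outlet_flows_L_s.values()):.12f} L/s"
      " (conserved)")

ak.export_bc(case, "bc_normal.csv")
print("wrote bc_normal.csv: 18 velocity inlets + 1 zero-pressure outlet")
# after the normal-geometry CFD run, re-use the orifice pressures as
# pressure inlets for the stenotic model (the equal-pressure transfer):
#   ak.export_bc(case, "bc_stenotic.csv", stage="stenotic_pressure_inlets",
#                pressures_Pa={...from ak.import_simulation_results(...)})
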