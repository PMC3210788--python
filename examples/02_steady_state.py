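"""Solve the undosed steady state and break down where the VEGF sits.

The healthy mouse secretes VEGF continuously; at steady state secretion is
balanced by internalisation of receptor-bound VEGF, plasma clearance and
(marginally) lymph flow.  Free VEGF is a tiny sliver of the total: most of
it is parked on myocyte NRP-1 and matrix binding sites.
"""

from vegfmouse import (ReactionNetwork, free_vegf_picomolar,
                       receptor_occupancy, solve_steady_state,
                       steady_state_flows, vegf_distribution)

net = ReactionNetwork()
steady = solve_steady_state(net)

blood, tissue = free_vegf_picomolar(net, steady)
print(f"unbound VEGF: blood {blood:.3f} pM, tissue {tissue:.2f} pM")
print("(the ~50-fold tissue excess is why plasma VEGF underestimates the")
print(" interstitial growth-factor environment)\n")

print("Flows at steady state, as % of secretion:")
for name, share in steady_state_flows(net, steady).normalized.items():
    print(f"  {name:28s} {100 * share:7.3f} %")
print("internalisation on myocytes and endothelium removes ~99% of output\n")

dist = vegf_distribution(net, steady)
print("Tissue VEGF by bound form (fractions):")
print(dist.table.loc["tissue", "total"].sort_values(ascending=False)
      .to_string(float_format="{:.3f}".format))

occ = receptor_occupancy(net, steady)
r2_unbound = occ.fraction("tissue", "R2", "unbound")
r2_ternary = occ.fraction("tissue", "R2", "ternary_V164")
print(f"\ntissue VEGFR-2: {100 * r2_unbound:.1f}% unbound, "
      f"{100 * r2_ternary:.1f}% in the VEGF164/NRP-1 ternary complex")
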