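"""Derive the tissue geometry and unit conversions from base measurements.

Starting from a handful of measured quantities (capillary density, fiber
cross-section, basement-membrane thicknesses, ...), the geometry module
produces every volume fraction, surface density and unit-conversion factor
the reaction network needs.
"""

from vegfmouse import derive_geometry, geometry_report

geo = derive_geometry()

print(f"tissue volume            {geo.tissue_volume:8.2f} cm^3")
print(f"capillary surface        {geo.capillary_surface_per_tissue:8.2f} cm^2/cm^3 tissue")
print(f"fiber surface            {geo.fiber_surface_per_tissue:8.2f} cm^2/cm^3 tissue")
print(f"available volume K_AV    {geo.k_av:8.4f} cm^3 fluid/cm^3 tissue")
print()
print("K_AV is the fraction of tissue a 45 kDa protein can actually occupy:")
print("interstitium minus collagen minus sterically excluded pore space.")
print("It converts between per-tissue amounts and interstitial molarity",
      f"(1 M = {geo.conversions['tissue_molar']:.3g} pmol/cm^3 tissue).")
print()
print(geometry_report(geo).to_string(index=False, float_format="{:.6g}".format))
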