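"""Oxide totals, total alkali and TAS classification for dust samples.

Loads the packaged bulk compositions of three geogenic particle samples
(Arizona test dust, Gobi Desert dust, St. Vincent volcanic ash) and
prints analytical totals and the TAS class of each.
"""

from importlib import resources

from geoparticle import geochem as gc

path = resources.files("geoparticle.data").joinpath("bulk_oxides.csv")
comps = gc.read_oxide_csv(str(path))
print(gc.classify_table(comps).to_string(index=False))
# The volcanic ash (54 wt.% SiO2, 4.1 wt.% Na2O+K2O) plots in the
# basaltic andesite field; the quartz-rich desert dusts fall at silica
# contents where the TAS scheme (built for magmatic rocks) is nominal.
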