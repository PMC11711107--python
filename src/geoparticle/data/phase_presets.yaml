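# Named element-set presets for common phases in geogenic dust EDS mapping.
# Editable: these are starting points, not fixed chemistry — thresholds and
# element choices should be tuned per instrument and scene.
quartz: [Si]
crystalline silica: [Si]
plagioclase feldspar: [Al, Si, Ca, Na]
potassium feldspar: [Al, Si, K]
calcite: [Ca]
mica/clay: [Al, Si, K, Mg]
pyroxene: [Si, Mg, Fe, Ca]
olivine: [Si, Mg, Fe]
iron oxides: [Fe]
iron-titanium oxides: [Fe, Ti]
glass: [Si, Al, Na]
anhydrite: [Ca, S]
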