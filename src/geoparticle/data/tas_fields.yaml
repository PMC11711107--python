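# Total-alkali–silica (TAS) field polygons, wt.% coordinates (SiO2, Na2O+K2O),
# after the standard Le Bas diagram. Editable: add or refine fields as needed.
# The very-high-alkali branch (tephrite/basanite, phonotephrite, tephriphonolite,
# phonolite, foidite) is not encoded; points there classify as "unclassified".
picrobasalt:
  - [41, 0]
  - [45, 0]
  - [45, 3]
  - [41, 3]
basalt:
  - [45, 0]
  - [52, 0]
  - [52, 5]
  - [45, 5]
basaltic andesite:
  - [52, 0]
  - [57, 0]
  - [57, 5.9]
  - [52, 5]
andesite:
  - [57, 0]
  - [63, 0]
  - [63, 7]
  - [57, 5.9]
dacite:
  - [63, 0]
  - [77, 0]
  - [69, 8]
  - [63, 7]
rhyolite:
  - [77, 0]
  - [100, 0]
  - [100, 13]
  - [69, 13]
  - [69, 8]
trachybasalt:
  - [45, 5]
  - [52, 5]
  - [49.4, 7.3]
  - [45, 9.4]
basaltic trachyandesite:
  - [52, 5]
  - [57, 5.9]
  - [53, 9.3]
  - [49.4, 7.3]
trachyandesite:
  - [57, 5.9]
  - [63, 7]
  - [57.6, 11.7]
  - [53, 9.3]
trachyte:
  - [63, 7]
  - [69, 8]
  - [69, 13]
  - [57.6, 11.7]
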