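# Device presets, lengths in mm.  Straight strips of 100 mm; looped strips
# of 150/160 mm with looped-region lengths 43 mm (single loop, 14 mm loop
# diameter) and 58 mm (double loop, 9 mm loop diameter).  vertical_extent is
# strip_length - loop_length (the measurable vertical span); the loop entry
# height of 20 mm is a documented assumption (not a measured value).
straight-100:
  strip_length_mm: 100
  n_loops: 0
  loop_length_mm: 0
  loop_diameter_mm: 0
  loop_entry_height_mm: 0
  vertical_extent_mm: 100
loop1-150:
  strip_length_mm: 150
  n_loops: 1
  loop_length_mm: 43
  loop_diameter_mm: 14
  loop_entry_height_mm: 20
  vertical_extent_mm: 107
loop2-160:
  strip_length_mm: 160
  n_loops: 2
  loop_length_mm: 58
  loop_diameter_mm: 9
  loop_entry_height_mm: 20
  vertical_extent_mm: 102
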