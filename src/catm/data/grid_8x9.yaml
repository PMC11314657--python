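# 8 x 9 flattening of the 32-electrode international 10-20 montage.
# Conventional arrangement used by 3D/4D EEG-CNN pipelines; cells without
# an electrode stay zero. Edit here to correct placements without code
# changes.
rows: 8
cols: 9
placement:
  Fp1: [0, 3]
  Fp2: [0, 5]
  AF3: [1, 3]
  AF4: [1, 5]
  F7: [2, 0]
  F3: [2, 2]
  Fz: [2, 4]
  F4: [2, 6]
  F8: [2, 8]
  FC5: [3, 0]
  FC1: [3, 2]
  FC2: [3, 6]
  FC6: [3, 8]
  T7: [4, 0]
  C3: [4, 2]
  Cz: [4, 4]
  C4: [4, 6]
  T8: [4, 8]
  CP5: [5, 0]
  CP1: [5, 2]
  CP2: [5, 6]
  CP6: [5, 8]
  P7: [6, 0]
  P3: [6, 2]
  Pz: [6, 4]
  P4: [6, 6]
  P8: [6, 8]
  PO3: [7, 1]
  O1: [7, 3]
  Oz: [7, 4]
  O2: [7, 5]
  PO4: [7, 7]
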