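{
 "channels": [
  "Fp1",
  "Fpz",
  "Fp2",
  "AF7",
  "AF3",
  "AFz",
  "AF4",
  "AF8",
  "F7",
  "F5",
  "F3",
  "F1",
  "Fz",
  "F2",
  "F4",
  "F6",
  "F8",
  "FT7",
  "FC5",
  "FC3",
  "FC1",
  "FCz",
  "FC2",
  "FC4",
  "FC6",
  "FT8",
  "T7",
  "C5",
  "C3",
  "C1",
  "Cz",
  "C2",
  "C4",
  "C6",
  "T8",
  "TP7",
  "CP5",
  "CP3",
  "CP1",
  "CPz",
  "CP2",
  "CP4",
  "CP6",
  "TP8",
  "P9",
  "P7",
  "P5",
  "P3",
  "P1",
  "Pz",
  "P2",
  "P4",
  "P6",
  "P8",
  "P10",
  "PO7",
  "PO3",
  "POz",
  "PO4",
  "PO8",
  "O1",
  "Oz",
  "O2",
  "Iz"
 ],
 "lobe_map": {
  "Fp1": "frontal",
  "Fpz": "frontal",
  "Fp2": "frontal",
  "AF7": "frontal",
  "AF3": "frontal",
  "AFz": "frontal",
  "AF4": "frontal",
  "AF8": "frontal",
  "F7": "frontal",
  "F5": "frontal",
  "F3": "frontal",
  "F1": "frontal",
  "Fz": "frontal",
  "F2": "frontal",
  "F4": "frontal",
  "F6": "frontal",
  "F8": "frontal",
  "FT7": "temporal",
  "FC5": "frontal",
  "FC3": "frontal",
  "FC1": "frontal",
  "FCz": "frontal",
  "FC2": "frontal",
  "FC4": "frontal",
  "FC6": "frontal",
  "FT8": "temporal",
  "T7": "temporal",
  "C5": "parietal",
  "C3": "parietal",
  "C1": "parietal",
  "Cz": "parietal",
  "C2": "parietal",
  "C4": "parietal",
  "C6": "parietal",
  "T8": "temporal",
  "TP7": "temporal",
  "CP5": "parietal",
  "CP3": "parietal",
  "CP1": "parietal",
  "CPz": "parietal",
  "CP2": "parietal",
  "CP4": "parietal",
  "CP6": "parietal",
  "TP8": "temporal",
  "P9": "parietal",
  "P7": "parietal",
  "P5": "parietal",
  "P3": "parietal",
  "P1": "parietal",
  "Pz": "parietal",
  "P2": "parietal",
  "P4": "parietal",
  "P6": "parietal",
  "P8": "parietal",
  "P10": "parietal",
  "PO7": "occipital",
  "PO3": "occipital",
  "POz": "occipital",
  "PO4": "occipital",
  "PO8": "occipital",
  "O1": "occipital",
  "Oz": "occipital",
  "O2": "occipital",
  "Iz": "occipital"
 }
}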