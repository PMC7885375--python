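{
 "name": "standard-1020-62ch",
 "version": 1,
 "channels": [
  {
   "label": "Fp1",
   "x": -0.5467,
   "y": 1.556,
   "hemisphere": "left",
   "homologue": "Fp2"
  },
  {
   "label": "Fp2",
   "x": 0.5467,
   "y": 1.556,
   "hemisphere": "right",
   "homologue": "Fp1"
  },
  {
   "label": "AF3",
   "x": -0.5412,
   "y": 1.2053,
   "hemisphere": "left",
   "homologue": "AF4"
  },
  {
   "label": "AF4",
   "x": 0.5412,
   "y": 1.2053,
   "hemisphere": "right",
   "homologue": "AF3"
  },
  {
   "label": "AF7",
   "x": -1.0562,
   "y": 1.3203,
   "hemisphere": "left",
   "homologue": "AF8"
  },
  {
   "label": "AF8",
   "x": 1.0562,
   "y": 1.3203,
   "hemisphere": "right",
   "homologue": "AF7"
  },
  {
   "label": "F1",
   "x": -0.3644,
   "y": 0.7322,
   "hemisphere": "left",
   "homologue": "F2"
  },
  {
   "label": "F2",
   "x": 0.3644,
   "y": 0.7322,
   "hemisphere": "right",
   "homologue": "F1"
  },
  {
   "label": "F3",
   "x": -0.7303,
   "y": 0.7685,
   "hemisphere": "left",
   "homologue": "F4"
  },
  {
   "label": "F4",
   "x": 0.7303,
   "y": 0.7685,
   "hemisphere": "right",
   "homologue": "F3"
  },
  {
   "label": "F5",
   "x": -1.1025,
   "y": 0.8151,
   "hemisphere": "left",
   "homologue": "F6"
  },
  {
   "label": "F6",
   "x": 1.1025,
   "y": 0.8151,
   "hemisphere": "right",
   "homologue": "F5"
  },
  {
   "label": "F7",
   "x": -1.4619,
   "y": 0.8864,
   "hemisphere": "left",
   "homologue": "F8"
  },
  {
   "label": "F8",
   "x": 1.4619,
   "y": 0.8864,
   "hemisphere": "right",
   "homologue": "F7"
  },
  {
   "label": "FT7",
   "x": -1.6784,
   "y": 0.3048,
   "hemisphere": "left",
   "homologue": "FT8"
  },
  {
   "label": "FT8",
   "x": 1.6784,
   "y": 0.3048,
   "hemisphere": "right",
   "homologue": "FT7"
  },
  {
   "label": "FT9",
   "x": -2.0746,
   "y": 0.3569,
   "hemisphere": "left",
   "homologue": "FT10"
  },
  {
   "label": "FT10",
   "x": 2.0746,
   "y": 0.3569,
   "hemisphere": "right",
   "homologue": "FT9"
  },
  {
   "label": "FC1",
   "x": -0.397,
   "y": 0.3024,
   "hemisphere": "left",
   "homologue": "FC2"
  },
  {
   "label": "FC2",
   "x": 0.397,
   "y": 0.3024,
   "hemisphere": "right",
   "homologue": "FC1"
  },
  {
   "label": "FC3",
   "x": -0.8106,
   "y": 0.3074,
   "hemisphere": "left",
   "homologue": "FC4"
  },
  {
   "label": "FC4",
   "x": 0.8106,
   "y": 0.3074,
   "hemisphere": "right",
   "homologue": "FC3"
  },
  {
   "label": "FC5",
   "x": -1.2396,
   "y": 0.305,
   "hemisphere": "left",
   "homologue": "FC6"
  },
  {
   "label": "FC6",
   "x": 1.2396,
   "y": 0.305,
   "hemisphere": "right",
   "homologue": "FC5"
  },
  {
   "label": "C1",
   "x": -0.3915,
   "y": -0.104,
   "hemisphere": "left",
   "homologue": "C2"
  },
  {
   "label": "C2",
   "x": 0.3915,
   "y": -0.104,
   "hemisphere": "right",
   "homologue": "C1"
  },
  {
   "label": "C3",
   "x": -0.7984,
   "y": -0.1358,
   "hemisphere": "left",
   "homologue": "C4"
  },
  {
   "label": "C4",
   "x": 0.7984,
   "y": -0.1358,
   "hemisphere": "right",
   "homologue": "C3"
  },
  {
   "label": "C5",
   "x": -1.2164,
   "y": -0.1973,
   "hemisphere": "left",
   "homologue": "C6"
  },
  {
   "label": "C6",
   "x": 1.2164,
   "y": -0.1973,
   "hemisphere": "right",
   "homologue": "C5"
  },
  {
   "label": "T7",
   "x": -1.6522,
   "y": -0.3031,
   "hemisphere": "left",
   "homologue": "T8"
  },
  {
   "label": "T8",
   "x": 1.6522,
   "y": -0.3031,
   "hemisphere": "right",
   "homologue": "T7"
  },
  {
   "label": "TP7",
   "x": -1.4481,
   "y": -0.7783,
   "hemisphere": "left",
   "homologue": "TP8"
  },
  {
   "label": "TP8",
   "x": 1.4481,
   "y": -0.7783,
   "hemisphere": "right",
   "homologue": "TP7"
  },
  {
   "label": "TP9",
   "x": -1.764,
   "y": -0.9607,
   "hemisphere": "left",
   "homologue": "TP10"
  },
  {
   "label": "TP10",
   "x": 1.764,
   "y": -0.9607,
   "hemisphere": "right",
   "homologue": "TP9"
  },
  {
   "label": "CP1",
   "x": -0.359,
   "y": -0.4585,
   "hemisphere": "left",
   "homologue": "CP2"
  },
  {
   "label": "CP2",
   "x": 0.359,
   "y": -0.4585,
   "hemisphere": "right",
   "homologue": "CP1"
  },
  {
   "label": "CP3",
   "x": -0.7183,
   "y": -0.5169,
   "hemisphere": "left",
   "homologue": "CP4"
  },
  {
   "label": "CP4",
   "x": 0.7183,
   "y": -0.5169,
   "hemisphere": "right",
   "homologue": "CP3"
  },
  {
   "label": "CP5",
   "x": -1.0869,
   "y": -0.6183,
   "hemisphere": "left",
   "homologue": "CP6"
  },
  {
   "label": "CP6",
   "x": 1.0869,
   "y": -0.6183,
   "hemisphere": "right",
   "homologue": "CP5"
  },
  {
   "label": "P1",
   "x": -0.2978,
   "y": -0.7924,
   "hemisphere": "left",
   "homologue": "P2"
  },
  {
   "label": "P2",
   "x": 0.2978,
   "y": -0.7924,
   "hemisphere": "right",
   "homologue": "P1"
  },
  {
   "label": "P3",
   "x": -0.5904,
   "y": -0.8549,
   "hemisphere": "left",
   "homologue": "P4"
  },
  {
   "label": "P4",
   "x": 0.5904,
   "y": -0.8549,
   "hemisphere": "right",
   "homologue": "P3"
  },
  {
   "label": "P5",
   "x": -0.8633,
   "y": -0.9721,
   "hemisphere": "left",
   "homologue": "P6"
  },
  {
   "label": "P6",
   "x": 0.8633,
   "y": -0.9721,
   "hemisphere": "right",
   "homologue": "P5"
  },
  {
   "label": "P7",
   "x": -1.1239,
   "y": -1.1319,
   "hemisphere": "left",
   "homologue": "P8"
  },
  {
   "label": "P8",
   "x": 1.1239,
   "y": -1.1319,
   "hemisphere": "right",
   "homologue": "P7"
  },
  {
   "label": "PO3",
   "x": -0.4237,
   "y": -1.166,
   "hemisphere": "left",
   "homologue": "PO4"
  },
  {
   "label": "PO4",
   "x": 0.4237,
   "y": -1.166,
   "hemisphere": "right",
   "homologue": "PO3"
  },
  {
   "label": "PO7",
   "x": -0.7619,
   "y": -1.3454,
   "hemisphere": "left",
   "homologue": "PO8"
  },
  {
   "label": "PO8",
   "x": 0.7619,
   "y": -1.3454,
   "hemisphere": "right",
   "homologue": "PO7"
  },
  {
   "label": "O1",
   "x": -0.3814,
   "y": -1.4455,
   "hemisphere": "left",
   "homologue": "O2"
  },
  {
   "label": "O2",
   "x": 0.3814,
   "y": -1.4455,
   "hemisphere": "right",
   "homologue": "O1"
  },
  {
   "label": "Fz",
   "x": 0.0,
   "y": 0.7219,
   "hemisphere": "midline",
   "homologue": "Fz"
  },
  {
   "label": "Cz",
   "x": 0.0,
   "y": -0.0912,
   "hemisphere": "midline",
   "homologue": "Cz"
  },
  {
   "label": "Pz",
   "x": 0.0,
   "y": -0.7762,
   "hemisphere": "midline",
   "homologue": "Pz"
  },
  {
   "label": "Oz",
   "x": 0.0,
   "y": -1.4439,
   "hemisphere": "midline",
   "homologue": "Oz"
  },
  {
   "label": "CPz",
   "x": 0.0,
   "y": -0.4442,
   "hemisphere": "midline",
   "homologue": "CPz"
  },
  {
   "label": "POz",
   "x": 0.0,
   "y": -1.1109,
   "hemisphere": "midline",
   "homologue": "POz"
  }
 ]
}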