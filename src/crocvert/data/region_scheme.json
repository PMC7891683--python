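{
  "positions": [
    "C2",
    "C3",
    "C4",
    "C5",
    "C6",
    "C7",
    "C8",
    "C9",
    "D1",
    "D2",
    "D3",
    "D4",
    "D5",
    "D6",
    "D7",
    "D8",
    "D9",
    "D10",
    "D11",
    "D12",
    "D13",
    "D14",
    "D15",
    "S1",
    "S2",
    "Ca1",
    "Ca2",
    "Ca3",
    "Ca4",
    "Ca5",
    "Ca6",
    "Ca7",
    "Ca8",
    "Ca9",
    "Ca10"
  ],
  "precaudal": [
    "C2",
    "C3",
    "C4",
    "C5",
    "C6",
    "C7",
    "C8",
    "C9",
    "D1",
    "D2",
    "D3",
    "D4",
    "D5",
    "D6",
    "D7",
    "D8",
    "D9",
    "D10",
    "D11",
    "D12",
    "D13",
    "D14",
    "D15",
    "S1",
    "S2"
  ],
  "caudal": [
    "Ca1",
    "Ca2",
    "Ca3",
    "Ca4",
    "Ca5",
    "Ca6",
    "Ca7",
    "Ca8",
    "Ca9",
    "Ca10"
  ],
  "regions": {
    "C2": [
      "C2"
    ],
    "C3-7ave": [
      "C3",
      "C4",
      "C5",
      "C6",
      "C7"
    ],
    "C8-D2ave": [
      "C8",
      "C9",
      "D1",
      "D2"
    ],
    "D3-10ave": [
      "D3",
      "D4",
      "D5",
      "D6",
      "D7",
      "D8",
      "D9",
      "D10"
    ],
    "D11-14ave": [
      "D11",
      "D12",
      "D13",
      "D14"
    ],
    "D15": [
      "D15"
    ],
    "S1-2ave": [
      "S1",
      "S2"
    ],
    "Ca1": [
      "Ca1"
    ],
    "Ca2-4ave": [
      "Ca2",
      "Ca3",
      "Ca4"
    ],
    "Ca5-10ave": [
      "Ca5",
      "Ca6",
      "Ca7",
      "Ca8",
      "Ca9",
      "Ca10"
    ]
  },
  "series": {
    "C2-9sum": [
      "C2",
      "C3",
      "C4",
      "C5",
      "C6",
      "C7",
      "C8",
      "C9"
    ],
    "D1-15sum": [
      "D1",
      "D2",
      "D3",
      "D4",
      "D5",
      "D6",
      "D7",
      "D8",
      "D9",
      "D10",
      "D11",
      "D12",
      "D13",
      "D14",
      "D15"
    ],
    "C2-D15sum": [
      "C2",
      "C3",
      "C4",
      "C5",
      "C6",
      "C7",
      "C8",
      "C9",
      "D1",
      "D2",
      "D3",
      "D4",
      "D5",
      "D6",
      "D7",
      "D8",
      "D9",
      "D10",
      "D11",
      "D12",
      "D13",
      "D14",
      "D15"
    ],
    "C2-Ca10sum": [
      "C2",
      "C3",
      "C4",
      "C5",
      "C6",
      "C7",
      "C8",
      "C9",
      "D1",
      "D2",
      "D3",
      "D4",
      "D5",
      "D6",
      "D7",
      "D8",
      "D9",
      "D10",
      "D11",
      "D12",
      "D13",
      "D14",
      "D15",
      "S1",
      "S2",
      "Ca1",
      "Ca2",
      "Ca3",
      "Ca4",
      "Ca5",
      "Ca6",
      "Ca7",
      "Ca8",
      "Ca9",
      "Ca10"
    ]
  },
  "region_statistic": "mean",
  "series_statistic": "sum"
}
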