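{
  "aliases": {
    "NF-kB": "nuclear_p50-p65-P",
    "p50-p65-P": "nuclear_p50-p65-P"
  },
  "components": [
    {
      "annotation": "",
      "default_level": 0,
      "max_level": 1,
      "name": "DSBs_early"
    },
    {
      "annotation": "",
      "default_level": 0,
      "max_level": 1,
      "name": "DSBs_late"
    },
    {
      "annotation": "",
      "default_level": 0,
      "max_level": 1,
      "name": "RPA-ATR-ATRIP-P"
    },
    {
      "annotation": "",
      "default_level": 0,
      "max_level": 1,
      "name": "ATM-P"
    },
    {
      "annotation": "",
      "default_level": 0,
      "max_level": 1,
      "name": "p53-P"
    },
    {
      "annotation": "",
      "default_level": 0,
      "max_level": 1,
      "name": "nuclear_p50-p65-P"
    }
  ],
  "outputs": [],
  "terms": [
    {
      "id": 1,
      "literals": [
        {
          "component": "DSBs_early",
          "negated": false,
          "threshold": 1
        }
      ],
      "target": "DSBs_late",
      "target_level": 1,
      "time_scale": 2
    },
    {
      "id": 2,
      "literals": [
        {
          "component": "DSBs_early",
          "negated": false,
          "threshold": 1
        },
        {
          "component": "p53-P",
          "negated": true,
          "threshold": 1
        }
      ],
      "target": "ATM-P",
      "target_level": 1,
      "time_scale": 1
    },
    {
      "id": 3,
      "literals": [
        {
          "component": "DSBs_late",
          "negated": false,
          "threshold": 1
        },
        {
          "component": "p53-P",
          "negated": true,
          "threshold": 1
        }
      ],
      "target": "RPA-ATR-ATRIP-P",
      "target_level": 1,
      "time_scale": 1
    },
    {
      "id": 4,
      "literals": [
        {
          "component": "ATM-P",
          "negated": false,
          "threshold": 1
        },
        {
          "component": "p53-P",
          "negated": true,
          "threshold": 1
        }
      ],
      "target": "p53-P",
      "target_level": 1,
      "time_scale": 1
    },
    {
      "id": 5,
      "literals": [
        {
          "component": "RPA-ATR-ATRIP-P",
          "negated": false,
          "threshold": 1
        },
        {
          "component": "p53-P",
          "negated": true,
          "threshold": 1
        }
      ],
      "target": "p53-P",
      "target_level": 1,
      "time_scale": 1
    },
    {
      "id": 6,
      "literals": [
        {
          "component": "ATM-P",
          "negated": false,
          "threshold": 1
        },
        {
          "component": "nuclear_p50-p65-P",
          "negated": true,
          "threshold": 1
        }
      ],
      "target": "nuclear_p50-p65-P",
      "target_level": 1,
      "time_scale": 1
    }
  ]
}
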