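{
  "functions": {
    "brainstem_serial": {
      "full_score": 7.0,
      "metric": "D0.03cc",
      "penalty": -150.0,
      "tolerance": 63.0,
      "type": "serial"
    },
    "ctv_coverage": {
      "cap": 7.0,
      "goal": 98.0,
      "goal_score": 4.996789609646667,
      "higher_is_better": true,
      "inner_slope": 1.0027319395622647,
      "metric": "V100",
      "outer_slope": 1.6664210087685252,
      "type": "piecewise"
    },
    "ctv_high_hotspot": {
      "cap": 7.0,
      "goal": 107.0,
      "goal_score": 4.980338572436773,
      "higher_is_better": false,
      "inner_slope": 0.4087367621131443,
      "metric": "Dmax",
      "outer_slope": 1.657369888222911,
      "type": "piecewise"
    },
    "oral_cavity_mean": {
      "cap": 7.0,
      "goal": 35.0,
      "goal_score": 5.005219918411646,
      "higher_is_better": false,
      "inner_slope": 0.9963887356900505,
      "metric": "Dmean",
      "outer_slope": 1.250798436356798,
      "type": "piecewise"
    },
    "parotid_mean": {
      "cap": 7.0,
      "goal": 26.0,
      "goal_score": 5.019305232410153,
      "higher_is_better": false,
      "inner_slope": 0.9822994013034582,
      "metric": "Dmean",
      "outer_slope": 1.2511218041666823,
      "type": "piecewise"
    },
    "spinal_cord_serial": {
      "full_score": 7.0,
      "metric": "D0.03cc",
      "penalty": -150.0,
      "tolerance": 54.0,
      "type": "serial"
    }
  },
  "score_cap": 7.0
}
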