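{
 "bonded": {
  "angles": {
   "CT-OH-HO": [
    55.0,
    107.3
   ],
   "CT-OS-CT": [
    62.0,
    113.8
   ],
   "HW-OW-HW": [
    100.0,
    104.52
   ],
   "X-CT-X": [
    50.0,
    109.5
   ]
  },
  "bonds": {
   "CT-CT": [
    310.0,
    1.52
   ],
   "CT-H1": [
    340.0,
    1.092
   ],
   "CT-H2": [
    340.0,
    1.092
   ],
   "CT-OH": [
    320.0,
    1.41
   ],
   "CT-OS": [
    285.0,
    1.41
   ],
   "OH-HO": [
    553.0,
    0.96
   ],
   "OW-HW": [
    553.0,
    0.9572
   ]
  },
  "dihedrals": {
   "CT-CT-CT-OS": [
    [
     0.16,
     3,
     0.0
    ]
   ],
   "CT-OS-CT-H2": [
    [
     0.0,
     3,
     0.0
    ]
   ],
   "OH-CT-CT-OS": [
    [
     0.75,
     2,
     0.0
    ],
    [
     0.14,
     3,
     0.0
    ]
   ],
   "OS-CT-CT-OS": [
    [
     0.82,
     2,
     0.0
    ],
    [
     0.1,
     3,
     0.0
    ]
   ],
   "X-CT-CT-X": [
    [
     0.156,
     3,
     0.0
    ]
   ],
   "X-CT-OH-X": [
    [
     0.18,
     3,
     0.0
    ]
   ],
   "X-CT-OS-X": [
    [
     0.3,
     3,
     0.0
    ]
   ]
  }
 },
 "dipole": {
  "axis_sign": {},
  "c": 0.8,
  "induced_enabled": {
   "CT-H1": true,
   "CT-H2": true,
   "CT-OH": false,
   "CT-OS": false,
   "OH-HO": true,
   "OW-HW": true
  },
  "mu0": {
   "CT-H1": 0.3,
   "CT-H2": 0.35,
   "CT-OH": 0.95,
   "CT-OS": 0.9,
   "OH-HO": 1.52,
   "OW-HW": 1.515
  },
  "q0": {
   "CT": 0.05,
   "H1": 0.085,
   "H2": 0.11,
   "HO": 0.2142,
   "HW": 0.191,
   "OH": -0.33,
   "OS": -0.29,
   "OW": -0.382
  },
  "site_fraction": 0.5
 },
 "k_dd": 14.39326229412817,
 "meta": {
  "name": "pbdp-placeholder",
  "provenance": "synthetic working set",
  "schema_version": 1
 },
 "orbital": {
  "angle_cut": 120.0,
  "classes": {
   "OH-HO...OW": {
    "D": 1.3,
    "R0": 2.85,
    "a": 2.0,
    "alpha0": 180.0,
    "beta0": 109.5,
    "p": 5
   },
   "OW-HW...OH": {
    "D": 1.25,
    "R0": 2.88,
    "a": 2.0,
    "alpha0": 180.0,
    "beta0": 109.5,
    "p": 5
   },
   "OW-HW...OS": {
    "D": 1.0,
    "R0": 2.95,
    "a": 2.0,
    "alpha0": 180.0,
    "beta0": 109.5,
    "p": 5
   },
   "OW-HW...OW": {
    "D": 1.2,
    "R0": 2.9,
    "a": 2.0,
    "alpha0": 180.0,
    "beta0": 109.5,
    "p": 5
   }
  },
  "r_cut": 3.5
 },
 "scaling": {
  "elec_min_bond_path": 3,
  "vdw14_scale": 0.5
 },
 "vdw": {
  "combining_rule": "lorentz-berthelot",
  "epsilon": {
   "CT": 0.1094,
   "H1": 0.0157,
   "H2": 0.0157,
   "HO": 0.0,
   "HW": 0.0,
   "OH": 0.2104,
   "OS": 0.17,
   "OW": 0.152
  },
  "rmin": {
   "CT": 3.816,
   "H1": 2.774,
   "H2": 2.574,
   "HO": 1.2,
   "HW": 1.2,
   "OH": 3.442,
   "OS": 3.367,
   "OW": 3.5364
  }
 }
}
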