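indicator_id,weight,nv_2000,nv_2005,nv_2012,nv_2015,nv_2020,nv_2030
C1,0.046,1,0.861,0.621,0.519,0.345,0
C2,0.051,0.090,0.099,0.553,0.470,0.647,1
C3,0.041,0,0.315,0.432,0.550,0.700,1
C4,0.052,0.025,0.641,0.398,0.373,0.542,0.880
C5,0.048,0,0.081,0.401,0.473,0.649,1
C6,0.052,1,0.532,0.283,0.270,0.101,0
C7,0.049,0,0.273,0.675,0.707,0.767,1
C8,0.047,0.082,0.147,0.450,0.495,0.663,1
C9,0.048,0.265,0.433,0.820,0.851,0.911,1
C10,0.063,0.868,0,0.917,0.936,0.957,1
C11,0.043,0.611,0.376,0.535,0.548,0.592,1
C12,0.059,0.075,0.450,0.805,0.847,0.932,1
C13,0.068,0,0.237,0.884,0.942,0.977,1
C14,0.044,0,0.030,0.139,0.212,0.374,1
C15,0.047,0,0.129,0.436,0.483,0.655,1
C16,0.047,0.114,0.036,0.311,0.571,0.643,1
C17,0.048,0,0.077,0.416,0.470,0.646,1
C18,0.048,0.950,0.681,0.451,0.486,0.324,0
C19,0.052,0,0.259,0.704,0.759,0.852,1
C20,0.047,0.492,1,0.719,0.418,0.337,0.037
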