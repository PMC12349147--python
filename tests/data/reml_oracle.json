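{
 "description": "REML estimates (intercept, sigma2_group, sigma2_resid) for the 50 seeded one-way random-intercept fixtures produced by tests/_oracles.py:reml_fixtures(seed=2024), computed with an independent mixed-model implementation (lme4 1.1-37, R 4.3.3).",
 "estimates": [
  [
   -1.24740963199698,
   0.225158978964816,
   0.0320255627742056
  ],
  [
   0.162797709221549,
   0.122490780348152,
   0.350969063048667
  ],
  [
   0.530577855003059,
   0.203803612574481,
   0.0422534998551594
  ],
  [
   0.609261668636632,
   0.100600587767545,
   0.0744960466076289
  ],
  [
   1.87984591892853,
   0.0642462917248856,
   0.0287589809660457
  ],
  [
   -2.43689234462823,
   0,
   0.485376776348873
  ],
  [
   0.153325892806492,
   0.0261054531029792,
   0.0460486128906676
  ],
  [
   1.19555311079373,
   0.768317511643438,
   0.159697484277006
  ],
  [
   -4.59583736690823,
   0,
   0.441923617728576
  ],
  [
   -0.495638754418921,
   0.132768745117373,
   0.0297518034642876
  ],
  [
   3.37791423962711,
   0,
   0.667109821346785
  ],
  [
   -2.26559911269016,
   0.257624051303079,
   0.212605460303209
  ],
  [
   0.0334864611123468,
   0.22060353445343,
   0.538580268279922
  ],
  [
   -0.710698526993119,
   0.089003736623061,
   0.689763934497774
  ],
  [
   -2.22756164849504,
   0.0559192833396417,
   0.595790798000967
  ],
  [
   -3.05500177241993,
   0.186187919981574,
   0.433114410267283
  ],
  [
   0.30178238428777,
   0.998982236944679,
   0.0895289859440365
  ],
  [
   0.908425755995937,
   0.325271555688154,
   0.0189402254106148
  ],
  [
   3.12202601860301,
   0.00417298052579541,
   0.262354386734407
  ],
  [
   1.00973242652565,
   0,
   0.160998738703167
  ],
  [
   1.68289388556985,
   0.274158275601499,
   0.195788425460264
  ],
  [
   -0.55469376775249,
   0.0720483735196274,
   0.34589024233057
  ],
  [
   -1.78346015476134,
   0.554496905985519,
   0.300919580151545
  ],
  [
   -0.387891976432255,
   0.0837399585886132,
   0.0247407650879473
  ],
  [
   -1.70652866937875,
   0.155722550714315,
   0.105274493983826
  ],
  [
   2.17635066582339,
   0.159925959578075,
   0.0178455777155817
  ],
  [
   -1.65483036786123,
   0.0112508766611095,
   0.903630343443697
  ],
  [
   -0.169579382721649,
   0,
   0.124442581053237
  ],
  [
   -3.64802964318854,
   0.375688698497133,
   0.055412996252978
  ],
  [
   -0.0754955800911577,
   0.015407327119136,
   0.532943925234166
  ],
  [
   0.6928377556462,
   5.30247672702708e-17,
   0.555571350030887
  ],
  [
   -4.83254063736891,
   1.23232141826623,
   0.488113032959018
  ],
  [
   0.933685633313279,
   0.276529807345578,
   0.276530150097048
  ],
  [
   1.28547374040335,
   0.746607893368829,
   0.0148394055798409
  ],
  [
   0.328257092991607,
   0.125655379236804,
   0.00922675455788445
  ],
  [
   0.207108233133932,
   0.184758404324291,
   0.443171908188054
  ],
  [
   -4.15558550444321,
   0.00807786394488135,
   0.70305344127024
  ],
  [
   -0.503481045183923,
   0.218078477026848,
   0.121269214889766
  ],
  [
   -0.929820855496315,
   0,
   0.201011567558385
  ],
  [
   -2.58759489290168,
   0.0952175982995462,
   0.0735554915540394
  ],
  [
   0.435352085096382,
   0.00566905341268745,
   0.596159525913801
  ],
  [
   1.21624001971777,
   0.310638825908475,
   0.0165310806064865
  ],
  [
   1.16373416231599,
   0.0200093426982504,
   0.775724298030925
  ],
  [
   -1.43861937531428,
   0.000697170756920722,
   0.273592846151447
  ],
  [
   -1.7849075931961,
   0.0233082549030027,
   0.111289326979893
  ],
  [
   -0.0927819802282902,
   1.04140849652269,
   0.389086512158156
  ],
  [
   -0.839973538472843,
   0.033461328811197,
   0.102585762402665
  ],
  [
   -0.637362602780411,
   0.524462596236944,
   0.221058356365439
  ],
  [
   -0.641163857304878,
   0.00434636839312676,
   0.370788572912524
  ],
  [
   -0.947241066491043,
   0.816082828005697,
   0.297464094551534
  ]
 ]
}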