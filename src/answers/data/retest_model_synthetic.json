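{
 "0": {
  "weights": [
   0.8339353282725486,
   0.16606467172745137
  ],
  "alphas": [
   1.18961324748845,
   6.557210790740652
  ],
  "betas": [
   1.040303547091088,
   30.026643101143183
  ]
 },
 "1": {
  "weights": [
   0.6767399486289987,
   0.3232600513710014
  ],
  "alphas": [
   0.8986756635254821,
   16.51563032453604
  ],
  "betas": [
   1.6345117006117436,
   31.40668370601398
  ]
 },
 "2": {
  "weights": [
   0.6065136862397191,
   0.393486313760281
  ],
  "alphas": [
   0.8913112629523136,
   18.30554529048234
  ],
  "betas": [
   3.4760970207765913,
   31.634278607747277
  ]
 },
 "3": {
  "weights": [
   0.6016697479061813,
   0.3983302520938188
  ],
  "alphas": [
   0.9649516185317185,
   17.007758688495784
  ],
  "betas": [
   5.104239669700546,
   31.645038647337735
  ]
 },
 "4": {
  "weights": [
   0.5863765260120101,
   0.4136234739879899
  ],
  "alphas": [
   1.194415335864169,
   16.015202392005886
  ],
  "betas": [
   4.912686725626245,
   31.330788733086866
  ]
 },
 "5": {
  "weights": [
   0.7937097923260636,
   0.20629020767393635
  ],
  "alphas": [
   1.305171210746183,
   19.15164118637905
  ],
  "betas": [
   6.460373667653952,
   31.272674274985587
  ]
 },
 "6": {
  "weights": [
   0.5799110737603353,
   0.4200889262396647
  ],
  "alphas": [
   0.9901333538269229,
   2.7603192200517483
  ],
  "betas": [
   7.378612491350501,
   8.470902266685195
  ]
 },
 "7": {
  "weights": [
   0.650435048732649,
   0.34956495126735093
  ],
  "alphas": [
   1.0188854713870057,
   3.441890662101343
  ],
  "betas": [
   6.662715330080163,
   9.332468838925983
  ]
 },
 "8": {
  "weights": [
   0.7096395809929014,
   0.2903604190070987
  ],
  "alphas": [
   1.580796012342272,
   5.703065440998409
  ],
  "betas": [
   6.9105769598988545,
   10.849602843284103
  ]
 },
 "9": {
  "weights": [
   0.37423374982212987,
   0.6257662501778701
  ],
  "alphas": [
   1.1485840057845296,
   3.3183937945380095
  ],
  "betas": [
   9.283930590871242,
   11.577337593507938
  ]
 },
 "10": {
  "weights": [
   0.45314404336133374,
   0.5468559566386664
  ],
  "alphas": [
   1.2582624685396269,
   3.6588046089827406
  ],
  "betas": [
   5.8804350149917965,
   11.8345723351712
  ]
 },
 "11": {
  "weights": [
   0.11820193986673051,
   0.8817980601332694
  ],
  "alphas": [
   1.7585096797934425,
   2.712514804925539
  ],
  "betas": [
   1.7779851281561112,
   11.190732882841505
  ]
 },
 "12": {
  "weights": [
   0.14682864276702512,
   0.853171357232975
  ],
  "alphas": [
   1.200706884852888,
   3.4960893856284754
  ],
  "betas": [
   3.6521031014504235,
   13.288227814084348
  ]
 },
 "13": {
  "weights": [
   0.11638738838566551,
   0.8836126116143346
  ],
  "alphas": [
   1.5477155507193285,
   4.290417092934498
  ],
  "betas": [
   4.026647483961197,
   15.389836036314303
  ]
 },
 "14": {
  "weights": [
   0.11624380378152746,
   0.8837561962184726
  ],
  "alphas": [
   1.3485694719695611,
   4.988759202325597
  ],
  "betas": [
   3.3011543915595105,
   15.887088769102345
  ]
 },
 "15": {
  "weights": [
   0.08919969228219427,
   0.9108003077178057
  ],
  "alphas": [
   1.296492005878907,
   4.879637375520605
  ],
  "betas": [
   2.827706330141023,
   16.453125110319895
  ]
 },
 "16": {
  "weights": [
   0.08036033054952624,
   0.9196396694504738
  ],
  "alphas": [
   1.5376067276076935,
   5.0061688072302
  ],
  "betas": [
   1.8493499366502097,
   16.716435056633625
  ]
 },
 "17": {
  "weights": [
   0.04481712743334334,
   0.9551828725666566
  ],
  "alphas": [
   1.7372333348008446,
   5.612482965419192
  ],
  "betas": [
   2.6134684762428346,
   18.09207892386103
  ]
 },
 "18": {
  "weights": [
   0.037722803314412856,
   0.9622771966855872
  ],
  "alphas": [
   1.6617536847561516,
   5.950044537589254
  ],
  "betas": [
   1.9688351687114518,
   18.713241445558428
  ]
 },
 "19": {
  "weights": [
   0.024242783383328415,
   0.9757572166166717
  ],
  "alphas": [
   1.8370996672615791,
   6.214284494862002
  ],
  "betas": [
   2.672504100250538,
   19.90641478653671
  ]
 },
 "20": {
  "weights": [
   0.026175473782138105,
   0.9738245262178619
  ],
  "alphas": [
   1.178670725559672,
   5.5804549564252115
  ],
  "betas": [
   1.780737870288661,
   21.0523343125736
  ]
 },
 "21": {
  "weights": [
   0.6695759792708242,
   0.33042402072917576
  ],
  "alphas": [
   9.027536258323769,
   2.9250335881881058
  ],
  "betas": [
   21.516776901031598,
   23.549228481688168
  ]
 },
 "22": {
  "weights": [
   0.6253190618737976,
   0.3746809381262024
  ],
  "alphas": [
   9.384213130554196,
   4.108946067385181
  ],
  "betas": [
   22.404495142608347,
   23.773432600119744
  ]
 },
 "23": {
  "weights": [
   0.016344812574449953,
   0.98365518742555
  ],
  "alphas": [
   1.2436493691733168,
   6.950004858635598
  ],
  "betas": [
   1.8312005247897396,
   26.432166878524082
  ]
 },
 "24": {
  "weights": [
   0.039420111361986546,
   0.9605798886380135
  ],
  "alphas": [
   0.9847348314318949,
   8.770283724888223
  ],
  "betas": [
   3.6294493863074355,
   28.49361804115642
  ]
 },
 "25": {
  "weights": [
   0.015566969311995414,
   0.9844330306880046
  ],
  "alphas": [
   1.442882898534506,
   12.782519672724122
  ],
  "betas": [
   3.1472876372292844,
   29.72057816110856
  ]
 },
 "26": {
  "weights": [
   0.02721482361115657,
   0.9727851763888434
  ],
  "alphas": [
   1.364166419462489,
   15.491502134348739
  ],
  "betas": [
   2.118715787067507,
   30.200197083804127
  ]
 },
 "27": {
  "weights": [
   0.02836879433157381,
   0.9716312056684262
  ],
  "alphas": [
   1.397002885741569,
   16.759731007346947
  ],
  "betas": [
   2.139396220641896,
   30.521532918011054
  ]
 },
 "28": {
  "weights": [
   0.023460410503997605,
   0.9765395894960025
  ],
  "alphas": [
   1.3628396706025134,
   17.56359428349175
  ],
  "betas": [
   2.0032775829169744,
   30.646541214181816
  ]
 },
 "29": {
  "weights": [
   0.021329032694550713,
   0.9786709673054493
  ],
  "alphas": [
   1.3513156965882136,
   17.831148463419325
  ],
  "betas": [
   2.173811904090512,
   30.88978402453735
  ]
 },
 "30": {
  "weights": [
   0.022076105879900026,
   0.9779238941201
  ],
  "alphas": [
   1.3616686932646178,
   18.44205726363984
  ],
  "betas": [
   2.0373782471285105,
   31.15089089884275
  ]
 },
 "31": {
  "weights": [
   0.022088828408744602,
   0.9779111715912554
  ],
  "alphas": [
   1.4067129418353952,
   19.09138491765754
  ],
  "betas": [
   2.14429164617323,
   31.483025988956445
  ]
 },
 "32": {
  "weights": [
   0.02093663892404687,
   0.9790633610759532
  ],
  "alphas": [
   1.4827778579721467,
   19.30204684020611
  ],
  "betas": [
   2.1661855969956805,
   31.988072265402813
  ]
 },
 "33": {
  "weights": [
   0.01948388922960735,
   0.9805161107703927
  ],
  "alphas": [
   1.5354125006821004,
   20.84324820119744
  ],
  "betas": [
   2.0575469407312164,
   32.554850048060594
  ]
 },
 "34": {
  "weights": [
   0.016348171876725943,
   0.983651828123274
  ],
  "alphas": [
   1.7271212562350993,
   21.931116686449457
  ],
  "betas": [
   2.1053894404863676,
   33.107595581782036
  ]
 },
 "35": {
  "weights": [
   0.017002081887578072,
   0.9829979181124219
  ],
  "alphas": [
   1.4724538711812738,
   23.11884227217995
  ],
  "betas": [
   1.9986020580511086,
   33.76866505466406
  ]
 }
}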