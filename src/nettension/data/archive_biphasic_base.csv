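iteration,seed,outcome,score,ke_MYC,d_MYC,k_CDm,k_CDs,d_CD,k_E2Fm,k_auto,k_tl,d_E2Fm,d_E2Fp,k_Adeg,k_RB,d_RB,k_phD,K_phD,k_phE,K_phE,k_deph,d_RP,k_CE,d_CE,k_A,d_A,k_X,K_XM,d_X,K_S,K_M,K_P,K_RB,K_X
0,1198373377,solution,1.0323746336266384,0.01,0.0102772253,0.15293486,3.04196475,0.015,1.3538739,1.94883593,1.55356219,1.33444858,9.2311642,0.358708211,0.00557592116,0.0584530633,0.714474011,0.282719083,639.556047,0.0520833153,0.0376962279,50.0,0.0511714043,0.665288128,0.001,1.82328231,2.23083812,1000.0,1.08653813,0.507139667,49.0830217,0.318009003,0.0036219412,0.0370423257
2,247616251,solution,1.269322433426199,0.0235963992,0.802722562,0.0200754882,1.05824627,0.368251813,0.0121982551,8.25091307,0.153026365,0.01,4.69589349,0.0005,0.00384849481,0.780528872,36.9216399,0.020275251,2.07500107,0.003,0.216169431,0.0699320117,0.0151106658,33.3801579,0.779421555,0.160267035,0.590482468,9.78549312,0.0350715456,1.51031392,0.139127361,13.1644705,0.00172736188,0.596601525
7,478624026,solution,1.92112585929972,9.64893675,70.0,0.278582537,0.0068051532,1.09766442,30.0,8.62426216,200.0,0.01,1.66619008,0.909000636,1.05356946,0.00147407246,0.42425186,0.218152491,3.72795941,0.0467928565,0.00569034893,50.0,1.46613333,0.257137998,0.0482964229,2.06512893,0.236672188,4.40144215,0.001,35.2186983,0.017031904,0.028305043,0.00104360548,0.972761155
10,1436905159,solution,0.9151742562168336,0.0528400189,4.0688286,0.0114901532,0.795474692,6.50170504,27.801672,0.19768561,47.3373201,2.24901412,27.7978385,0.0184770745,0.016320615,0.726324899,0.716539194,14.2239674,6.07345082,0.0404169023,8.97177636,11.1462081,68.4057243,0.346525418,1.17122191,0.055836426,0.0039566695,0.648579854,0.0587166858,33.9651647,0.241243025,1.9515204,4.40252066,0.005
15,1249102037,solution,1.8179380189900884,0.01287968,0.007,1.88198035,0.46837641,3.15131912,0.0184084526,51.2384341,55.3908297,4.17129677,1.04758234,5.0,4.57927941,3.31053901,7.56500102,0.003,1.62108327,0.713329862,0.0798363365,0.005,0.947233241,0.0464751023,0.783605791,0.001,0.002,0.130511588,8.83846369,0.632059043,14.5665128,3.02638718,0.979090085,0.0509673847
17,555775056,solution,1.239634153764256,9.63909428,14.2475459,0.0549488342,0.00620571007,0.159756542,6.78455692,0.0965887021,20.5899573,1.26847427,13.0610427,0.00845243725,0.835360281,0.0308930614,58.239261,0.0496221916,1380.26223,16.8143265,1.55747865,0.300157667,0.445882422,27.0614771,0.0787494918,0.317320589,1.36708902,72.025199,0.00190040222,0.0916496631,2.0440222,140.243447,0.907511171,0.0182499872
24,934019276,solution,1.8529916778351159,34.4032723,2.85765126,0.725018996,0.0275578042,0.0940716695,0.13141386,6.1652978,133.621477,0.955694758,42.1852649,0.00144024944,1.25953954,0.00267632762,500.0,0.075339755,193.806473,0.0109296648,15.2747685,0.0087340901,37.3631037,0.25625434,0.00598318772,0.0194985132,0.826085423,688.761294,0.0816252225,0.0287824612,0.721352242,0.0241375546,0.0413130239,0.130410098
26,1936883394,solution,0.9838934972468196,0.40994268,0.116845471,0.0499513205,0.553760402,29.55364,30.0,0.12348189,20.275643,0.0382367708,21.4936251,0.305945138,0.0618654608,0.00256893993,1.19024616,0.00738473842,108.07975,0.003,0.0279555816,0.0230855952,0.465147453,47.3596327,0.0140277419,2.71466586,0.886882986,196.445673,0.0148901658,2.56665646,1.23696268,0.038597388,0.0104443081,15.9371647
28,139658340,solution,1.1867408911464468,0.0403806731,0.0584845571,0.159355348,0.462416926,0.827319138,2.99103793,0.180964198,0.31684881,0.253098649,2.04189422,0.0106459088,0.330645989,0.016892134,0.0621697516,0.0939409814,5.48782949,0.108984812,0.0041645368,0.880054148,78.1297484,6.61588863,0.00123348792,1.62891147,0.0382531896,2.98151997,0.00119560219,0.906598382,0.0880328194,10.2760035,0.818404331,1.983178
38,1804935661,solution,0.8269789855773182,1.61483118,8.71319638,100.0,1.05745202,38.9825251,0.29000475,200.0,41.6105586,12.3737784,0.0907793701,0.140467453,7.9976654,0.00987066836,16.7377691,0.0229855322,2.61530999,0.0471994234,0.0193459737,0.365565037,0.602014297,14.66745,0.0105876748,2.4253972,0.409109837,9.20664172,1.27188281,2.3459872,0.116496179,0.02,10.0,0.178296264
51,187759249,solution,1.2372104759682787,0.0183902921,0.97378319,0.322368173,0.0195867803,0.0209698374,0.310090724,0.168782469,0.169557832,0.270393282,0.0414343539,0.016849112,0.378860835,0.00187646986,37.6064891,0.0949540763,60.4891909,0.0102635078,28.567168,0.005,6.86270736,0.0148225272,0.00170249878,6.3206517,0.239687433,3.07603112,0.0113313213,0.961118793,0.0501084426,0.0973358566,10.0,0.0372947758
65,525733631,solution,0.9817758128828147,0.529062632,4.28639201,4.28729398,0.390629675,0.307865235,1.21930947,0.809208867,0.0234769465,0.059812676,0.273020671,0.000587353177,10.21242,0.326886281,443.107131,6.53665331,48.6102829,3.70235718,11.8122676,0.081259367,0.358555891,59.202037,2.03073752,6.32807113,0.0207359102,3.06407885,0.186987844,0.776165112,0.133243468,2.34604156,0.222201188,0.0332092785
78,1064419981,solution,1.2280999045007392,0.240474847,37.7097851,0.394075955,10.9185536,3.5199145,3.89757386,200.0,2.28708045,0.295680763,0.01,0.0005,16.6825621,0.0141184016,500.0,0.012046555,6.51850594,0.0643945016,1.39039167,0.0104628621,1.70776054,1.61917628,0.00875126407,3.8363329,0.112550481,0.751186067,0.00139128321,1.48404603,0.642098269,7.84511874,0.309192287,1.11380706
83,1718667864,solution,1.0000005952063105,0.0218606703,22.4006594,0.63013403,2.34713174,14.506657,12.105264,135.989392,82.8091119,38.3968383,0.0609393942,0.383990431,4.17332231,0.0154725285,2.88791218,0.290095078,7.40001423,0.0039518948,0.003,2.29505502,50.5494175,0.147986107,0.044935187,1.5336486,2.29585577,1.45210985,0.275332446,43.5081614,0.0106294207,4.11969781,0.0211746073,0.466563429
84,1269680200,solution,0.8673303586831285,0.0211178545,30.4624593,0.0232283145,0.0683049293,0.736130568,0.427000159,17.308484,2.44758958,0.785918054,2.64534316,0.00151434872,0.00385009287,1.37760955,0.41231305,0.0357681773,9.05259947,0.00451311388,2.89453921,30.9929132,1.10402775,0.01,0.00864795872,0.0356273919,4.02104447,35.8335956,0.0149477188,3.74796245,4.12494197,20.9471488,0.00337058939,0.209525465
90,2112498558,solution,1.1290515829687255,0.0101419534,12.9892176,0.60124167,0.058366812,0.908157819,30.0,1.27119187,1.46133232,0.0104972689,0.01,0.0360057304,0.0522637999,0.00441243525,0.420843237,0.958971533,0.337119076,0.0273587013,0.0370531198,0.132891293,0.146583339,9.91242871,0.195444271,2.57055136,0.0564474802,0.733706077,0.0631318709,0.821404011,0.0125133379,0.02,0.0030594934,0.0132618284
99,2054665796,solution,0.9912554902522467,0.192356046,0.0478819804,0.0698167273,5.12562854,0.015,20.3532063,0.310919524,0.0543397247,59.0665883,0.01,3.24526043,0.0322282741,0.352767596,500.0,0.0372854356,2.74188008,0.0105227585,4.53000398,0.0154564644,14.4418224,22.9935898,0.757753617,1.07051415,20.0,666.473181,0.305676162,13.6087989,9.72319778,0.187095604,0.185983083,20.8748464
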