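town,population,adult_population,objects_offered,refusals,n_capture1,n_capture2,recaptures_def1,recaptures_def2,misidentified,distributor_recaptures
Mbale,FSW,161720,143,32,111,156,31,25,5,d1:6;d2:19
Jinja,FSW,144280,103,8,95,194,23,23,6,d1:7;d2:16
Busia,FSW,98210,117,9,108,169,22,19,0,d1:7;d2:16
Tororo,FSW,155520,66,7,59,146,16,3,1,d1:3;d2:0
Masaka,FSW,91680,130,4,126,138,50,34,0,d1:15;d2:19
Wakiso,FSW,786970,105,3,102,146,18,18,0,d1:1;d2:17
Mbarara,FSW,156270,155,5,150,203,16,16,0,d1:16;d2:0
Kabale,FSW,75809,86,21,65,110,22,19,0,d1:9;d2:10
Gulu,FSW,88820,141,8,133,225,32,21,2,d1:10;d2:11
Kabarole,FSW,90307,112,10,102,183,55,47,0,d1:5;d2:42
Mukono,FSW,194920,159,9,150,242,116,113,2,d1:5;d2:109
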