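pre,post,strength,sign,reliability,significant,control
T01,T02,594.9509053354706,1,0.9802718935870774,True,False
T03,T04,598.7356059354037,1,0.9792354790273141,True,False
T05,T06,604.0799961541095,1,0.9857879606116655,True,False
T07,T08,606.5256402391333,1,0.9871337721705428,True,False
T09,T10,580.1375782129485,-1,0.9795239040315413,True,False
T11,T12,575.3479256598501,-1,0.9753401792813176,True,False
T13,T14,2.481811778754503,-1,-0.030392446461046833,False,False
T15,T16,0.21726613410538534,1,-0.0421932977954385,False,False
T17,T18,2.3743100841357303,-1,-0.001387229724197736,False,False
T19,T20,0.27446735211881285,1,-0.04517493644095827,False,False
T21,T22,4.593707548641505,-1,-0.032103859312090595,False,True
T23,T24,1.9707219299681296,1,-0.05752516029858717,False,True
T25,T26,16.324480791811634,-1,-0.02002088252355577,False,True
T27,T28,2.6385354317180676,-1,0.014445209698843038,False,True
T29,T30,0.7537631219126862,1,-0.032457904401516004,False,True
T31,T32,0.5032079891531599,-1,-0.03554230488718549,False,True
T33,T34,0.6054134010730259,1,0.003700088075445677,False,True
T35,T36,19.201437763131363,-1,0.05222848894469602,False,True
T37,T38,0.777536781736883,1,-0.04010214929608228,False,True
T39,T40,3.0539182631262847,1,-0.09575858408330301,False,True
T41,T42,2.9145878233119205,1,-0.07366000646529347,False,True
T43,T44,5.845113015334334,1,0.0634134905408024,False,True
T45,T46,0.8990290884443239,-1,0.00650368385441473,False,True
T47,T48,1.6471393359709616,1,0.02744219713514111,False,True
T49,T50,27.28190318051325,-1,-0.05876234716183168,False,True
T51,T52,12.885809087650944,1,0.11671888641464453,False,True
T53,T54,21.990374879652705,-1,-0.049554966797869415,False,True
T55,T56,0.5385319567518563,-1,-0.045968024809783674,False,True
T57,T58,0.19257689114054335,1,-0.04188784994826992,False,True
T59,T60,0.22861784162867188,1,-0.016448011821651277,False,True
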