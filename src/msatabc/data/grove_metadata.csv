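population_id,lat,long,area,families,n,A_R,H_E,H_O,group,abc_deme
Placer,39.057,-120.574,1,4,8,2.08,0.29,0.25,none,
N Calaveras,38.279,-120.302,24,8,29,3.34,0.58,0.50,calaveras,Calaveras
S Calaveras,38.247,-120.240,184,8,21,3.57,0.63,0.53,calaveras,Calaveras
Tuolumne,37.769,-119.807,8,7,8,2.65,0.53,0.32,none,TuolumneMerced
Merced,37.750,-119.839,8,2,8,3.05,0.55,0.56,none,TuolumneMerced
Mariposa,37.509,-119.604,101,5,15,3.52,0.654,0.51,mariposa_nelder,MariposaNelder
Nelder,37.435,-119.590,195,8,29,3.73,0.696,0.58,mariposa_nelder,MariposaNelder
McKinley,37.023,-119.105,22,7,19,3.31,0.570,0.57,mckinley,McKinley
Cabin Creek,36.806,-118.941,40,7,21,3.40,0.619,0.55,south,South
Converse Basin,36.809,-118.977,1498,10,21,3.71,0.673,0.63,south,South
Lockwood,36.793,-118.841,40,4,10,3.52,0.622,0.55,south,South
Windy Gulch,36.766,-118.811,405,3,13,4.07,0.683,0.61,south,South
Grant,36.750,-118.984,130,2,2,,,0.55,south,South
Redwood Mtn,36.694,-118.916,1271,7,17,3.48,0.593,0.52,south,South
Giant Forest,36.565,-118.752,855,5,17,3.72,0.637,0.57,south,South
Atwell Mill,36.468,-118.674,383,7,18,3.70,0.631,0.60,south,South
Mountain Home,36.358,-118.706,97,4,8,3.70,0.624,0.57,south,South
Black Mtn 1,36.230,-118.681,1620,4,17,3.68,0.623,0.54,south,South
Black Mtn 2,36.140,-118.513,498,6,30,3.63,0.622,0.49,south,South
Wheel Meadow,36.118,-118.679,669,9,13,3.83,0.650,0.60,south,South
Packsaddle,36.102,-118.649,669,5,16,2.94,0.555,0.47,south,South
South Fork,35.929,-118.592,137,5,12,4.00,0.653,0.64,south,South
Deer Creek,35.872,-118.609,21,4,5,2.82,0.520,0.33,south,South
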