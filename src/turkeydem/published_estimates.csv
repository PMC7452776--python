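parameter,reference,adult,yearling,combined
nesting,Pollentier Lutz et al. 2014,0.90,0.34,
nesting,Shields & Flake 2006,0.94,0.91,
nesting,Porter et al. 1983,0.96,0.88,
nesting,Paisley et al. 1998,0.98,0.79,
nesting,Vander Haegen et al. 1988,1.00,0.81,
nesting,Vangilder & Kurzejeski 1995,,,0.97
nesting,Vangilder et al. 1987,,,1.00
nest_survival,Paisley et al. 1998,0.16,0.05,
nest_survival,Pollentier Lutz et al. 2014,0.23,0.12,
nest_survival,Vangilder & Kurzejeski 1995,0.35,0.20,
nest_survival,Vangilder et al. 1987,,,0.31
nest_survival,Shields & Flake 2006,0.51,0.47,
nest_survival,Porter et al. 1983,0.64,0.61,
nest_survival,Vander Haegen et al. 1988,0.68,0.33,
renesting,Shields & Flake 2006,0.51,0.22,
renesting,Vangilder & Kurzejeski 1995,0.39,0.46,
renesting,Pollentier Lutz et al. 2014,0.41,0.00,
renesting,Vander Haegen et al. 1988,,,0.50
renesting,Vangilder et al. 1987,,,0.55
renesting,Paisley et al. 1998,0.60,0.42,
renesting,Porter et al. 1983,,,0.65
clutch,Vangilder et al. 1987,,,10.03
clutch,Vangilder & Kurzejeski 1995,,,10.38
clutch,Pollentier Lutz et al. 2014,,,10.67
clutch,Paisley et al. 1998,11.2,10.3,
clutch,Vander Haegen et al. 1988,11.7,12.8,
clutch,Porter et al. 1983,12.8,11.1,
hatchability,Porter et al. 1983,0.76,0.83,
hatchability,Vander Haegen et al. 1988,0.83,0.86,
hatchability,Paisley et al. 1998,,,0.87
hatchability,Vangilder & Kurzejeski 1995,,,0.90
hatchability,Pollentier Lutz et al. 2014,,,0.92
poult_survival,Shields & Flake 2006,,,0.36
poult_survival,Pollentier Lutz et al. 2014,,,0.37
poult_survival,Vangilder et al. 1987,,,0.381
poult_survival,Hubbard et al. 1999,,,0.40
poult_survival,Roberts & Porter 1998,,,0.41
poult_survival,Vangilder & Kurzejeski 1995,,,0.45
poult_survival,Paisley et al. 1998,,,0.47
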