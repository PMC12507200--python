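residue	pc1	pc2	pc3	pc4	pc5	pc6	pc7	pc8	pc9	pc10	pc11	pc12	pc13	pc14	pc15
A	-0.77027406	-1.57913736	-0.27956482	1.11419055	1.69881403	-0.76428484	-1.21650339	-0.12250215	-1.65663208	0.49337848	1.07485920	1.13792540	-0.92955518	-0.51148429	-1.10539836
C	-0.50414880	-0.64820180	-0.42871405	-1.08024452	0.15502862	-0.48199793	2.65896168	-0.22413490	-0.90599948	-1.18695306	-0.67148035	0.73538961	0.34114348	-0.48426723	-0.36739945
D	-1.23013154	0.79663134	2.03562527	0.15058083	-0.62520538	0.40188403	-0.02178602	-0.21377899	-0.98548583	0.49535825	-0.79696776	-0.46848719	0.85315263	1.82315683	0.64211476
E	-0.57612500	0.70236134	2.44347975	1.69687069	0.43981150	0.81157424	-0.29694244	0.69146385	0.58636259	-1.28529719	-0.02286398	0.51633530	-0.24220254	-1.34886822	0.12356260
F	1.45313543	-0.57225280	0.62274099	-1.07180623	0.86172077	-0.10148500	-0.09416705	0.94857050	1.12432923	-0.75120653	0.46383682	1.89801364	2.35156341	0.27634250	-0.18950006
G	-2.00364266	-0.41346984	-0.99509731	-1.42883417	0.69330339	0.48938959	-0.66688727	2.44099728	0.04113244	0.37007901	0.26240689	-1.38666889	0.47729395	-0.64671795	1.25012188
H	0.50669254	0.71646905	0.13691968	-0.54742191	1.67495598	-1.85966911	-1.43744890	-1.20433766	-0.11880414	-1.62017502	-0.78806741	-1.71800947	0.12095485	0.53053248	0.19123093
I	0.62029254	-1.45286521	-0.23394634	0.71676778	-1.75477521	0.38948577	-0.64120738	0.97099202	0.35367020	-0.23494336	-1.02095232	-0.54093364	0.09771457	-0.23195063	-0.38626336
K	0.42765806	1.14317820	-1.58340660	1.14247961	0.73919433	0.56284957	-0.54697850	-1.00787844	1.18136073	1.70386291	0.18346059	0.20751924	1.58279476	-0.11021035	0.50957049
L	0.62289420	-1.41654675	-0.05160824	0.78196800	-0.59830445	0.43577638	-0.39703039	-0.97182894	-0.70127000	0.58637621	-1.39805733	0.32705771	0.17776046	-1.07564112	1.64306900
M	0.60750784	-0.73863318	0.32801652	0.56123472	1.80087875	0.64280038	2.12351776	-0.01475111	1.12265839	1.13212889	-1.04061873	-1.62606025	-0.78574324	0.20059206	-0.84949987
N	-0.78923036	0.94697598	-0.02827742	-0.41342180	-0.83932908	-0.62513246	0.75924450	-1.26243613	-1.39316876	0.79658826	0.27720847	-0.06977125	1.39167439	-1.45861309	-0.33779568
P	-0.74553784	-0.02018272	-0.56119945	-1.23760320	-0.28226126	2.84365033	-0.77619194	-1.81699288	0.57514149	-1.23384433	0.57635294	-0.06844116	-0.58379756	0.02613941	-1.28588919
Q	-0.12683888	0.84720938	0.28509491	0.83809164	-0.66017583	-0.51209704	0.67888259	0.72329155	0.21199677	0.61971904	2.19200403	-0.68702508	0.12547129	0.33957234	-1.37466817
R	0.76802471	1.86652916	-2.06254737	1.37712241	-0.28747671	0.33517711	0.40145888	1.27506463	-1.06306149	-1.60901186	-0.66580580	0.31756059	-0.56214038	0.35821291	0.05940238
S	-1.33838327	0.31354133	-0.35965153	-0.38723278	-0.11454942	-0.63437347	-0.25836160	0.13193556	0.81876169	0.98018782	-1.35078918	2.08092291	-1.14501129	1.98434905	-0.29701872
T	-0.50118252	0.03624343	-0.11066682	-0.03450923	-0.71546095	-1.29691590	0.71828855	-0.82159116	1.94329850	-0.54731268	1.28540215	0.33458608	-1.51489249	-0.69078711	2.08992405
V	0.36761159	-1.72252344	-0.30295671	0.53695117	-1.39247739	-0.69992178	-0.11762210	-0.31938580	0.01803817	-0.59608586	1.05786617	-1.00630468	0.56284539	1.72873753	-0.20158472
W	2.09575537	0.37664092	0.65612586	-1.24115420	0.36755009	1.06981213	0.15230873	0.25285048	-1.57845836	0.85987415	1.28959914	0.20478987	-1.35437098	0.71658029	1.45728760
Y	1.11592266	0.81803298	0.48963369	-1.47402936	-1.16124178	-1.00652198	-1.02153571	0.54445231	0.42612994	1.02727687	-0.90739355	-0.18839873	-0.96465552	-1.42567539	-1.57126610
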