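taxon	PH	LA	LMA	LT	LD	AR	RSR
sp01	2.292467976	1.038716648	2.286086271	6.087915312	11.75625271	1.128121387	6.48090773
sp02	0.9366166485	3.486588059	5.957569295	4.917417496	7.804777679	0.7221083573	3.148627026
sp03	1.389303536	1.71984832	9.264541835	13.44334119	4.950346902	2.750820592	2.97699971
sp04	2.401037976	2.950182349	7.858848314	5.69590734	15.25898215	0.3151862678	3.126695445
sp05	1.9321094	1.861981965	6.335757766	4.054394974	15.40051224	0.6729374877	3.198452152
sp06	2.067659721	1.125754427	4.966682717	3.992163469	6.008031489	2.25297372	2.984428179
sp07	1.305248339	0.9199058323	5.972688889	4.748005302	11.59002136	3.521701281	4.34017521
sp08	0.895296944	0.6052494523	2.499966997	4.034103944	3.672879126	2.736973417	2.940188413
sp09	1.89010533	0.9985866288	1.00214947	2.571626154	3.549318226	1.50710568	2.764724863
sp10	1.086087084	0.4505904716	1.936743797	3.162882225	5.090689694	1.756000496	7.312886138
sp11	0.5473544953	0.2032491697	1.856776999	1.0914008	1.658287719	2.46848424	1.333683721
sp12	0.7909336163	0.2416521397	2.505226563	1.086309397	1.073971861	0.3898040122	1.639404648
sp13	0.6478807658	0.1705636449	2.957109475	0.5950603372	0.7045383849	0.1063818982	0.6813083491
sp14	0.7133075758	0.2713721893	27.11190751	5.997861357	7.105552659	0.8229738992	2.749876123
sp15	7.99955144	0.9016800484	1.179231871	1.101931584	0.897175187	2.084718343	1.048490279
sp16	3.140733134	0.5252227442	1.387143566	1.138500551	0.6031663781	3.550436845	0.8788496824
sp17	0.7478831554	0.1469815434	1.212327874	0.4763343018	1.273332526	0.2450507191	1.268314633
sp18	1.02876655	0.2987654368	0.7631887336	0.659029258	2.341961316	3.404148198	0.8942764835
sp19	0.8903109493	0.2009769971	0.6628163502	0.5333537782	1.113536054	1.70917823	0.7733320562
sp20	1.288483663	0.5784934242	0.8405440404	1.358882852	1.07737923	0.6300054324	0.8625454131
sp21	1.08664568	0.210584811	0.9048633583	0.4464357037	1.565479037	0.5233030229	0.5943145725
sp22	0.5818049439	0.1742698957	0.8378568191	0.3686090775	0.5917798425	0.8934779223	0.4316140772
sp23	2.66252669	2.645181565	8.300895681	9.675925276	3.318069969	5.130451384	5.966196163
sp24	2.727973232	5.057469336	0.2006798586	0.4751896917	0.1247857046	0.7118564182	0.1344363587
sp25	1.705751292	2.762324748	4.62891267	6.733703454	1.637715865	0.5513604011	3.827223796
sp26	2.072481237	1.326137877	5.928971651	9.25908795	3.738982249	0.189074483	6.134924276
sp27	1.150951397	2.085497572	3.194184234	7.525119394	3.185834546	0.3411497619	3.60622472
sp28	1.887716021	3.974915404	0.840376986	0.6640039545	0.4154657953	2.785146579	1.263386736
sp29	0.7551858744	1.29339553	9.842872244	5.132218158	2.036468805	1.554391792	8.205630586
sp30	1.033477353	2.298672534	6.14505864	11.27145883	3.245529906	1.916529461	5.380450718
sp31	1.310615507	2.048931442	10.0404289	12.35347618	3.028732918	2.022450068	10.0713876
sp32	1.236481932	0.9680836686	5.779711075	1.959655824	2.902506002	0.6929097986	2.047519942
sp33	2.151305106	0.6754258043	4.209934446	1.978932482	6.862982588	1.009808424	3.887066972
sp34	2.950994583	1.342669452	9.712684019	2.317181338	2.459035228	0.9009472671	2.104979284
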